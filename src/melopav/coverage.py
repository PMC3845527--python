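"""Per-gene read counts, breadth of coverage and library-size normalization.

The counting contract mirrors region queries on a coordinate-sorted,
indexed BAM with unmapped reads excluded and a minimum mapping quality of
1: every alignment record overlapping the queried interval by at least one
base is counted, duplicates and secondary records are *not* filtered, and
counting is strand-blind. Counts can equivalently be loaded from a TSV
matrix written by this module (or by the synthetic-cohort generator), whose
last row ``__library_size__`` carries the per-cultivar total mapped reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

LIBRARY_SIZE_ROW = "__library_size__"
#: scaling constant for library-size normalization: counts per 10 million
#: mapped reads. Pairwise cross-cultivar ratios are invariant to this choice.
NORM_SCALE = 10_000_000


# ----------------------------------------------------------------------
# BAM counting
# ----------------------------------------------------------------------
def _qualifies(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not read.is_unmapped and read.mapping_quality >= min_mapq


def count_reads_in_interval(
    alignments: pysam.AlignmentFile,
    scaffold: str,
    start: int,
    end: int,
    min_mapq: int = 1,
) -> int:
    """Number of qualifying alignment records overlapping ``scaffold:start-end``.

    ``start``/``end`` are 1-based inclusive (the samtools region convention).
    A record qualifies if it is mapped with MAPQ >= ``min_mapq``; any >= 1 bp
    overlap counts. Raises ``ValueError`` for an unknown scaffold and
    ``OSError`` if the BAM has no index.
    """
    if scaffold not in alignments.references:
        raise ValueError(f"unknown scaffold {scaffold!r}")
    return sum(
        1
        for read in alignments.fetch(scaffold, start - 1, end)
        if _qualifies(read, min_mapq)
    )


def total_mapped_reads(alignments: pysam.AlignmentFile, min_mapq: int = 1) -> int:
    """Genome-wide qualifying read count (same filters as interval counting)."""
    total = 0
    for scaffold in alignments.references:
        total += sum(1 for read in alignments.fetch(scaffold) if _qualifies(read, min_mapq))
    return total


def breadth_in_interval(
    alignments: pysam.AlignmentFile,
    scaffold: str,
    start: int,
    end: int,
    min_mapq: int = 1,
) -> float:
    """Fraction of interval positions covered by >= 1 qualifying read.

    Coverage follows the aligned blocks of each read (deletions/skips in the
    read alignment do not contribute), matching a per-base pileup.
    """
    if scaffold not in alignments.references:
        raise ValueError(f"unknown scaffold {scaffold!r}")
    lo, hi = start - 1, end
    covered = np.zeros(hi - lo, dtype=bool)
    for read in alignments.fetch(scaffold, lo, hi):
        if not _qualifies(read, min_mapq):
            continue
        for bstart, bend in read.get_blocks():
            a, b = max(bstart, lo), min(bend, hi)
            if a < b:
                covered[a - lo : b - lo] = True
    return float(covered.mean()) if covered.size else 0.0


# ----------------------------------------------------------------------
# Matrices
# ----------------------------------------------------------------------
class CountMatrix:
    """Genes x cultivars raw read counts plus per-cultivar library sizes."""

    def __init__(self, counts: pd.DataFrame, library_sizes: pd.Series):
        counts = counts.copy()
        library_sizes = library_sizes.reindex(counts.columns)
        if counts.isna().any().any():
            gene, cult = _first_bad_cell(counts, counts.isna())
            raise ValueError(f"missing count at gene {gene!r}, cultivar {cult!r}")
        if (counts < 0).any().any():
            gene, cult = _first_bad_cell(counts, counts < 0)
            raise ValueError(f"negative count at gene {gene!r}, cultivar {cult!r}")
        if library_sizes.isna().any():
            missing = library_sizes.index[library_sizes.isna()][0]
            raise ValueError(f"missing library size for cultivar {missing!r}")
        short = library_sizes < counts.max(axis=0)
        if short.any():
            cult = library_sizes.index[short][0]
            raise ValueError(
                f"library size for cultivar {cult!r} is smaller than its largest gene count"
            )
        self.counts = counts.astype(np.int64)
        self.library_sizes = library_sizes.astype(np.int64)

    @property
    def cultivars(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def normalize(self, scale: int = NORM_SCALE) -> pd.DataFrame:
        """Counts rescaled to reads per ``scale`` total mapped reads.

        Zeros are preserved exactly; a zero library size is an error.
        """
        if (self.library_sizes <= 0).any():
            cult = self.library_sizes.index[self.library_sizes <= 0][0]
            raise ValueError(f"non-positive library size for cultivar {cult!r}")
        return self.counts * (scale / self.library_sizes)

    # -- TSV round trip -------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc[LIBRARY_SIZE_ROW] = self.library_sizes
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        counts, libs = _read_matrix_tsv(path, integer=True)
        return cls(counts, libs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        cols = sorted(self.counts.columns)
        if sorted(other.counts.columns) != cols:
            return False
        return self.counts[cols].equals(other.counts[cols]) and self.library_sizes[
            cols
        ].equals(other.library_sizes[cols])


class BreadthMatrix:
    """Genes x cultivars fraction of gene bases covered by >= 1 read."""

    def __init__(self, breadth: pd.DataFrame):
        if breadth.isna().any().any():
            gene, cult = _first_bad_cell(breadth, breadth.isna())
            raise ValueError(f"missing breadth at gene {gene!r}, cultivar {cult!r}")
        bad = (breadth < 0) | (breadth > 1)
        if bad.any().any():
            gene, cult = _first_bad_cell(breadth, bad)
            raise ValueError(f"breadth outside [0,1] at gene {gene!r}, cultivar {cult!r}")
        self.breadth = breadth.astype(float)

    def to_tsv(self, path) -> None:
        out = self.breadth.copy()
        # shape-compatible with the count writer; the sentinel row is ignored
        # on read
        out.loc[LIBRARY_SIZE_ROW] = 1.0
        out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "BreadthMatrix":
        values, _libs = _read_matrix_tsv(path, integer=False)
        return cls(values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BreadthMatrix):
            return NotImplemented
        cols = sorted(self.breadth.columns)
        if sorted(other.breadth.columns) != cols:
            return False
        return np.allclose(self.breadth[cols], other.breadth[cols], atol=1e-9)


def _first_bad_cell(df: pd.DataFrame, mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, cult = stacked[stacked].index[0]
    return str(gene), str(cult)


def _read_matrix_tsv(path, integer: bool) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if LIBRARY_SIZE_ROW not in df.index:
        raise ValueError(f"{path}: missing {LIBRARY_SIZE_ROW!r} row")
    libs = pd.to_numeric(df.loc[LIBRARY_SIZE_ROW], errors="coerce")
    values = df.drop(index=LIBRARY_SIZE_ROW).apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        gene, cult = _first_bad_cell(values, values.isna())
        raise ValueError(f"{path}: non-numeric or missing cell at row {gene!r}, column {cult!r}")
    if integer:
        as_int = values.round().astype(np.int64)
        if not np.allclose(values, as_int):
            gene, cult = _first_bad_cell(values, (values != as_int))
            raise ValueError(f"{path}: non-integer count at row {gene!r}, column {cult!r}")
        values = as_int
    return values, libs


# ----------------------------------------------------------------------
# BAM -> matrices
# ----------------------------------------------------------------------
def count_matrix_from_bams(
    bam_paths: dict[str, str],
    genes,
    min_mapq: int = 1,
    with_breadth: bool = False,
) -> CountMatrix | tuple[CountMatrix, BreadthMatrix]:
    """Count reads per gene for each cultivar's indexed BAM.

    ``bam_paths`` maps cultivar name to BAM path; ``genes`` is a
    :class:`~melopav.genes.GeneTable`.
    """
    counts = {}
    breadths = {}
    libs = {}
    for cultivar, path in bam_paths.items():
        with pysam.AlignmentFile(path, "rb") as bam:
            col = {}
            bcol = {}
            for gene_id in genes.gene_ids:
                scaffold, start0, end0 = genes.region(gene_id)
                col[gene_id] = count_reads_in_interval(
                    bam, scaffold, start0 + 1, end0, min_mapq=min_mapq
                )
                if with_breadth:
                    bcol[gene_id] = breadth_in_interval(
                        bam, scaffold, start0 + 1, end0, min_mapq=min_mapq
                    )
            libs[cultivar] = total_mapped_reads(bam, min_mapq=min_mapq)
        counts[cultivar] = col
        if with_breadth:
            breadths[cultivar] = bcol
    cm = CountMatrix(
        pd.DataFrame(counts).loc[genes.gene_ids], pd.Series(libs, dtype=np.int64)
    )
    if with_breadth:
        return cm, BreadthMatrix(pd.DataFrame(breadths).loc[genes.gene_ids])
    return cm
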