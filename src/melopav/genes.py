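"""Gene annotation backbone.

A :class:`GeneTable` holds the ordered gene models of one genome assembly.
Positional rank (0-based index of a gene among the genes of its scaffold,
sorted by start coordinate) is the backbone used for tandem-cluster
detection, so it is computed once at construction and kept consistent.

Coordinates are stored 0-based half-open internally; all I/O (GFF3, BED,
region strings) uses the 1-based inclusive convention of those formats.
"""

from __future__ import annotations

import io
from typing import Iterable

import pandas as pd

_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand"]


class GeneTable:
    """Ordered gene records across scaffolds.

    Parameters
    ----------
    records
        Iterable of ``(gene_id, scaffold, start, end, strand)`` tuples with
        0-based half-open coordinates, or a DataFrame with those columns.
    """

    def __init__(self, records: Iterable[tuple] | pd.DataFrame):
        if isinstance(records, pd.DataFrame):
            df = records.loc[:, _COLUMNS].reset_index(drop=True)
        else:
            df = pd.DataFrame(list(records), columns=_COLUMNS)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise ValueError(f"empty or inverted interval for gene {bad!r}")
        df = df.sort_values(["scaffold", "start", "gene_id"], kind="mergesort")
        df["rank"] = df.groupby("scaffold", sort=False).cumcount()
        df["length"] = df["end"] - df["start"]
        self.df = df.set_index("gene_id", drop=False)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.df["scaffold"]))

    def lengths(self) -> pd.Series:
        """Gene length in bp, indexed by gene_id."""
        return self.df["length"]

    def rank_of(self, gene_id: str) -> int:
        return int(self.df.at[gene_id, "rank"])

    def region(self, gene_id: str) -> tuple[str, int, int]:
        """``(scaffold, start, end)`` of a gene, 0-based half-open."""
        row = self.df.loc[gene_id]
        return str(row["scaffold"]), int(row["start"]), int(row["end"])

    def by_scaffold(self, scaffold: str) -> pd.DataFrame:
        return self.df[self.df["scaffold"] == scaffold]

    # ------------------------------------------------------------------
    # GFF3 I/O (genes only, ID= attribute)
    # ------------------------------------------------------------------
    @classmethod
    def from_gff3(cls, path) -> "GeneTable":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
                if ftype != "gene":
                    continue
                gene_id = None
                for attr in attrs.split(";"):
                    if attr.startswith("ID="):
                        gene_id = attr[3:]
                        break
                if gene_id is None:
                    raise ValueError(f"gene without ID attribute: {line!r}")
                records.append((gene_id, seqid, int(start) - 1, int(end), strand))
        return cls(records)

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_gff3_string())

    def to_gff3_string(self) -> str:
        buf = io.StringIO()
        buf.write("##gff-version 3\n")
        for row in self.df.itertuples(index=False):
            buf.write(
                f"{row.scaffold}\tmelopav\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )
        return buf.getvalue()

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
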