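"""Multi-copy gene families from filtered pairwise nucleotide homology hits.

Hits come in the de facto 12-column tabular alignment format
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore). A hit survives when its e-value is at most 1e-20 and
both the query and the subject gene are covered over more than 40% of
their length. Surviving hits become undirected edges; gene families are
the connected components (single-linkage closure) with at least two
members, and every gene without a surviving edge is a singleton.
"""

from __future__ import annotations

import pandas as pd
import networkx as nx

from .simulate import HIT_COLUMNS


def read_hits(path) -> pd.DataFrame:
    """Read a headerless 12-column tabular hit file."""
    hits = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                       dtype={"qseqid": str, "sseqid": str})
    return hits


def filter_hits(
    hits: pd.DataFrame,
    gene_lengths: pd.Series,
    e_max: float = 1e-20,
    cov_min: float = 0.40,
    identity_min: float | None = None,
    reciprocal: bool = False,
    hsp_mode: str = "best",
) -> set[frozenset]:
    """Filter hits and return the surviving undirected edge set.

    Coverage of each side is ``(qend - qstart + 1) / gene_length`` computed
    from one HSP per directed gene pair — the highest-bitscore one by
    default (``hsp_mode="best"``), or the union of non-overlapping HSP
    spans (``hsp_mode="summed"``). Both coverages must exceed ``cov_min``
    (strictly) and the e-value must be at most ``e_max``. Self-hits are
    dropped. By default an edge exists when *either* direction passes;
    ``reciprocal=True`` demands both.

    ``identity_min`` optionally imposes a percent-identity floor; it is off
    by default — high identity is an observed property of surviving
    nucleotide hits, not a filter.
    """
    if hsp_mode not in ("best", "summed"):
        raise ValueError(f"unknown hsp_mode {hsp_mode!r}")
    unknown = set(hits["qseqid"]).union(hits["sseqid"]) - set(gene_lengths.index)
    if unknown:
        raise ValueError(f"hit references unknown gene {sorted(unknown)[0]!r}")

    hits = hits[hits["qseqid"] != hits["sseqid"]]
    if identity_min is not None:
        hits = hits[hits["pident"] >= identity_min]
    hits = hits[hits["evalue"] <= e_max]

    passing: set[tuple[str, str]] = set()
    for (q, s), grp in hits.groupby(["qseqid", "sseqid"], sort=False):
        qlen = float(gene_lengths[q])
        slen = float(gene_lengths[s])
        if hsp_mode == "best":
            row = grp.loc[grp["bitscore"].idxmax()]
            qcov = (row["qend"] - row["qstart"] + 1) / qlen
            scov = (row["send"] - row["sstart"] + 1) / slen
        else:
            qcov = _union_span(grp["qstart"], grp["qend"]) / qlen
            scov = _union_span(grp["sstart"], grp["send"]) / slen
        for cov, gene in ((qcov, q), (scov, s)):
            if cov > 1.5:
                raise ValueError(
                    f"coverage {cov:.2f} > 1.5 for gene {gene!r}: "
                    "hit coordinates inconsistent with annotation"
                )
        if qcov > cov_min and scov > cov_min:
            passing.add((q, s))

    if reciprocal:
        return {frozenset(p) for p in passing if (p[1], p[0]) in passing}
    return {frozenset(p) for p in passing}


def _union_span(starts: pd.Series, ends: pd.Series) -> int:
    ivals = sorted(zip(starts.astype(int), ends.astype(int)))
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivals:
        s, e = min(s, e), max(s, e)
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def build_families(
    edges: set[frozenset], all_genes
) -> tuple[dict[str, list[str]], set[str]]:
    """Connected components of the homology graph.

    Returns ``(families, singletons)``: families maps a deterministic
    family id (``F_`` + lexicographically smallest member) to its sorted
    members (>= 2); singletons are all genes without a surviving edge.
    """
    graph = nx.Graph()
    all_genes = list(all_genes)
    graph.add_nodes_from(all_genes)
    for edge in edges:
        a, b = tuple(edge)
        graph.add_edge(a, b)
    families: dict[str, list[str]] = {}
    singletons: set[str] = set()
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            singletons.update(comp)
        else:
            members = sorted(comp)
            families[f"F_{members[0]}"] = members
    return families, singletons


def family_size_distribution(
    families: dict[str, list[str]], n_genes_total: int
) -> pd.DataFrame:
    """Per-size family counts and percentages plus cohort-level shares.

    The returned frame is indexed by family size with columns
    ``n_families``, ``pct_families`` (of all multi-copy families),
    ``n_genes`` and ``pct_multi_genes``; cohort-level shares (singleton
    fraction, size-band shares of multi-copy genes) are in ``df.attrs``.
    """
    sizes = pd.Series([len(m) for m in families.values()], dtype=int)
    n_families = len(sizes)
    n_multi = int(sizes.sum())
    tab = sizes.value_counts().sort_index().rename("n_families").to_frame()
    tab["pct_families"] = (100.0 * tab["n_families"] / n_families).round(1) if n_families else 0.0
    tab["n_genes"] = tab.index * tab["n_families"]
    tab["pct_multi_genes"] = (100.0 * tab["n_genes"] / n_multi).round(1) if n_multi else 0.0
    tab.index.name = "family_size"
    bands = {"2-3": (2, 3), "4-6": (4, 6), "7-20": (7, 20)}
    tab.attrs["singleton_fraction_pct"] = round(
        100.0 * (n_genes_total - n_multi) / n_genes_total, 1
    ) if n_genes_total else 0.0
    tab.attrs["n_families"] = n_families
    tab.attrs["n_multi_copy_genes"] = n_multi
    tab.attrs["band_share_of_multi_genes_pct"] = {
        name: round(100.0 * int(sizes[(sizes >= lo) & (sizes <= hi)].sum()) / n_multi, 1)
        if n_multi
        else 0.0
        for name, (lo, hi) in bands.items()
    }
    return tab


def write_families(families: dict[str, list[str]], singletons: set[str], outdir) -> None:
    """families.tsv (gene_id, family_id, family_size) + singletons.txt."""
    from pathlib import Path

    outdir = Path(outdir)
    rows = [
        (g, fam, len(members))
        for fam, members in sorted(families.items())
        for g in members
    ]
    pd.DataFrame(rows, columns=["gene_id", "family_id", "family_size"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False
    )
    with open(outdir / "singletons.txt", "w") as fh:
        for g in sorted(singletons):
            fh.write(g + "\n")


def read_families(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        fam: sorted(grp["gene_id"]) for fam, grp in df.groupby("family_id")
    }
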