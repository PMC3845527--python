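"""Tandem-cluster detection on the annotation backbone.

A tandem cluster is a run of two or more same-family genes on one
scaffold in which consecutive members are separated by at most
``max_intervening`` other annotated genes (default 8, i.e. "fewer than
nine genes between homologs"). Intervening genes are counted from
positional ranks and include members of other families; chaining is
transitive along the run. Clusters are built within families, so two
spatially interleaved families yield two separate clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genes import GeneTable


@dataclass
class TandemCluster:
    cluster_id: str
    scaffold: str
    family_id: str
    members: list[str]  # ordered by positional rank
    span: tuple[int, int]  # min start, max end (0-based half-open)

    def __len__(self) -> int:
        return len(self.members)


def detect_clusters(
    families: dict[str, list[str]],
    genes: GeneTable,
    max_intervening: int = 8,
) -> list[TandemCluster]:
    """Chain family members along each scaffold into positional clusters."""
    clusters: list[TandemCluster] = []
    df = genes.df
    for family_id in sorted(families):
        members = families[family_id]
        missing = [g for g in members if g not in genes]
        if missing:
            raise ValueError(
                f"gene {missing[0]!r} of family {family_id!r} missing from annotation"
            )
        sub = df.loc[members]
        for scaffold, sgenes in sub.groupby("scaffold", sort=True):
            sgenes = sgenes.sort_values("rank")
            chain: list[str] = []
            prev_rank = None
            for row in sgenes.itertuples():
                if prev_rank is not None and (row.rank - prev_rank - 1) > max_intervening:
                    _flush(clusters, chain, scaffold, family_id, df)
                    chain = []
                chain.append(row.gene_id)
                prev_rank = row.rank
            _flush(clusters, chain, scaffold, family_id, df)
    clusters.sort(key=lambda c: (c.scaffold, c.span[0], c.cluster_id))
    return clusters


def _flush(clusters, chain, scaffold, family_id, df) -> None:
    if len(chain) < 2:
        return
    starts = df.loc[chain, "start"]
    ends = df.loc[chain, "end"]
    clusters.append(
        TandemCluster(
            cluster_id=f"C_{min(chain)}",
            scaffold=str(scaffold),
            family_id=family_id,
            members=list(chain),
            span=(int(starts.min()), int(ends.max())),
        )
    )


def cluster_size_distribution(clusters: list[TandemCluster]) -> pd.DataFrame:
    """Per-size cluster counts/percentages; shares of clustered genes in
    long (>= 5-member) clusters are in ``df.attrs``."""
    sizes = pd.Series([len(c) for c in clusters], dtype=int)
    tab = sizes.value_counts().sort_index().rename("n_clusters").to_frame()
    n = len(clusters)
    tab["pct_clusters"] = (100.0 * tab["n_clusters"] / n).round(1) if n else 0.0
    tab.index.name = "cluster_size"
    n_genes = int(sizes.sum())
    tab.attrs["n_clusters"] = n
    tab.attrs["n_clustered_genes"] = n_genes
    tab.attrs["share_genes_in_clusters_ge5_pct"] = (
        round(100.0 * int(sizes[sizes >= 5].sum()) / n_genes, 1) if n_genes else 0.0
    )
    return tab


def override_membership(
    clusters: list[TandemCluster],
    overrides_path,
    genes: GeneTable,
    families: dict[str, list[str]],
) -> list[TandemCluster]:
    """Apply curated membership overrides from a directive file.

    Two directives are supported, one per line::

        merge <cluster_id> <cluster_id>   # same family, same scaffold
        add <gene_id> <cluster_id>        # gene must belong to the family

    Every applied override is logged with its source line. Directives that
    would mix families are rejected with an error.
    """
    import logging

    log = logging.getLogger(__name__)
    by_id = {c.cluster_id: c for c in clusters}
    gene_family = {g: f for f, mem in families.items() for g in mem}
    with open(overrides_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split("#")[0].split()
            if not parts:
                continue
            if parts[0] == "merge" and len(parts) == 3:
                a, b = by_id.get(parts[1]), by_id.get(parts[2])
                if a is None or b is None:
                    raise ValueError(f"line {lineno}: unknown cluster id")
                if a.family_id != b.family_id:
                    raise ValueError(
                        f"line {lineno}: cannot merge clusters of different "
                        f"families ({a.family_id} vs {b.family_id})"
                    )
                if a.scaffold != b.scaffold:
                    raise ValueError(f"line {lineno}: clusters on different scaffolds")
                merged = sorted(set(a.members) | set(b.members), key=genes.rank_of)
                a.members = merged
                a.span = (min(a.span[0], b.span[0]), max(a.span[1], b.span[1]))
                del by_id[b.cluster_id]
                log.info("override line %d: merged %s into %s", lineno, b.cluster_id, a.cluster_id)
            elif parts[0] == "add" and len(parts) == 3:
                gene, cl = parts[1], by_id.get(parts[2])
                if cl is None:
                    raise ValueError(f"line {lineno}: unknown cluster id {parts[2]!r}")
                if gene_family.get(gene) != cl.family_id:
                    raise ValueError(
                        f"line {lineno}: gene {gene!r} is not in family {cl.family_id!r}"
                    )
                if gene not in cl.members:
                    cl.members = sorted(set(cl.members) | {gene}, key=genes.rank_of)
                    _scaffold, start, end = genes.region(gene)
                    cl.span = (min(cl.span[0], start), max(cl.span[1], end))
                log.info("override line %d: added %s to %s", lineno, gene, cl.cluster_id)
            else:
                raise ValueError(f"line {lineno}: unrecognized override directive {line!r}")
    return sorted(by_id.values(), key=lambda c: (c.scaffold, c.span[0], c.cluster_id))


def clustered_genes(clusters: list[TandemCluster]) -> set[str]:
    return {g for c in clusters for g in c.members}


def write_clusters(clusters: list[TandemCluster], genes: GeneTable, outdir) -> None:
    """clusters.tsv (cluster_id, scaffold, gene_id, rank, family_id) + BED spans."""
    from pathlib import Path

    outdir = Path(outdir)
    rows = [
        (c.cluster_id, c.scaffold, g, genes.rank_of(g), c.family_id)
        for c in clusters
        for g in c.members
    ]
    pd.DataFrame(
        rows, columns=["cluster_id", "scaffold", "gene_id", "rank", "family_id"]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    bed = pd.DataFrame(
        [(c.scaffold, c.span[0], c.span[1], c.cluster_id) for c in clusters],
        columns=["chrom", "start", "end", "name"],
    )
    bed.to_csv(outdir / "clusters.bed", sep="\t", index=False, header=False)


def read_clusters(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "gene_id": str})
    return {cl: list(grp["gene_id"]) for cl, grp in df.groupby("cluster_id")}
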