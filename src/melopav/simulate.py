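"""Synthetic resequencing cohort generator.

Emulates the data layout of a plant pan-genome read-depth study: ~27k
annotated genes spread over scaffolds, five cultivars resequenced at
13-16x fold-coverage, about a quarter of genes in multi-copy families
(many of them tandem arrays), and planted full or partial gene deletions
that are enriched in multi-copy and clustered genes. Every downstream
stage (counting, PAV screens, family building, cluster detection,
enrichment) can be exercised offline against the planted truth.

No sequence-level simulation is attempted: the generator produces the
annotation (GFF3), per-gene read-count and breadth matrices, pairwise
homology hits in 12-column tabular format, and the ground-truth deletion
records.

Randomness is organised as one independent stream per sub-generator
(annotation, deletion truth, counts, homology hits), all derived from the
master seed, so e.g. changing the number of decoy hits does not perturb
the simulated counts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import BreadthMatrix, CountMatrix
from .genes import GeneTable

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

DEFAULT_CULTIVARS = ("DHL92", "T111", "PI161375", "C-836", "C-1012")


def _default_family_size_weights() -> dict[int, float]:
    """Family-size distribution: 64% two-member, 16% three-member families,
    with a geometric tail out to 20 members carrying the remaining mass."""
    weights = {2: 0.64, 3: 0.16}
    tail = np.array([0.75 ** (k - 4) for k in range(4, 21)])
    tail *= 0.20 / tail.sum()
    for k, w in zip(range(4, 21), tail):
        weights[k] = float(w)
    return weights


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions the generator emulates: a 454 Mb
    genome with 27,427 genes, 75.3% singletons, five cultivars at ~13-16x
    depth with 150 bp reads, a reference cultivar that carries no planted
    deletions, and deletion odds multiplied 5x for multi-copy genes and a
    further 2x for genes sitting in tandem arrays.
    """

    n_genes: int = 27427
    n_scaffolds: int = 50
    mean_gene_len: int = 2400  # bp
    mean_intergenic: int = 14000  # bp; with gene length gives ~450 Mb genome
    singleton_fraction: float = 0.753
    family_size_weights: dict[int, float] = field(
        default_factory=_default_family_size_weights
    )
    p_tandem: float = 0.4
    cultivars: tuple[str, ...] = DEFAULT_CULTIVARS
    reference: str = "DHL92"
    depth_per_cultivar: float | dict[str, float] = 15.0
    read_len: int = 150
    # per gene per non-reference cultivar; with the default multipliers,
    # ~25% multi-copy genes and the segment-run extension this realizes
    # ~1.5% of genes absent per cultivar
    base_del_rate: float = 0.0037
    multi_copy_multiplier: float = 5.0
    cluster_multiplier: float = 2.0
    segment_del_prob: float = 0.3
    segment_run_mean: float = 3.0  # genes
    partial_del_prob: float = 0.25
    background_mismap_rate: float = 0.0  # reads per kb of deleted sequence
    overdispersion: float = 0.0  # NB dispersion; 0 -> Poisson
    seed: int = 0

    def depth_of(self, cultivar: str) -> float:
        if isinstance(self.depth_per_cultivar, dict):
            return float(self.depth_per_cultivar[cultivar])
        return float(self.depth_per_cultivar)

    def validate(self) -> None:
        probs = {
            "singleton_fraction": self.singleton_fraction,
            "p_tandem": self.p_tandem,
            "base_del_rate": self.base_del_rate,
            "segment_del_prob": self.segment_del_prob,
            "partial_del_prob": self.partial_del_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if abs(sum(self.family_size_weights.values()) - 1.0) > 1e-6:
            raise ValueError("family_size_weights must sum to 1")
        if any(k < 2 for k in self.family_size_weights):
            raise ValueError("family sizes must be >= 2")
        for c in self.cultivars:
            if self.depth_of(c) <= 0:
                raise ValueError(f"depth for cultivar {c!r} must be positive")
        if self.reference not in self.cultivars:
            raise ValueError(f"reference {self.reference!r} not among cultivars")
        if self.multi_copy_multiplier < 1 or self.cluster_multiplier < 1:
            raise ValueError("rate multipliers must be >= 1")
        if self.segment_run_mean < 1:
            raise ValueError("segment_run_mean must be >= 1")
        if self.n_scaffolds < 1 or self.n_genes < self.n_scaffolds:
            raise ValueError("need at least one gene per scaffold")

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("annotation", "truth", "counts", "hits")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class FamilyTruth:
    """Planted family architecture: family members and tandem placement."""

    members: dict[str, list[str]]  # family_id -> gene ids
    tandem: dict[str, bool]  # family_id -> placed as a tandem run

    @property
    def multi_copy_genes(self) -> set[str]:
        return {g for mem in self.members.values() for g in mem}

    @property
    def clustered_genes(self) -> set[str]:
        return {
            g
            for fam, mem in self.members.items()
            if self.tandem[fam]
            for g in mem
        }

    def family_sets(self) -> set[frozenset]:
        return {frozenset(m) for m in self.members.values()}


@dataclass
class DeletionTruth:
    """Planted deletions: ``(gene_id, cultivar, kind, retained_fraction)``.

    ``kind`` is ``"full"`` (retained fraction 0) or ``"partial"`` (retained
    fraction strictly between 0 and 1). The reference cultivar never appears.
    """

    records: list[tuple[str, str, str, float]]

    def __len__(self) -> int:
        return len(self.records)

    def retained_matrix(self, genes: GeneTable, cultivars) -> pd.DataFrame:
        retained = pd.DataFrame(
            1.0, index=genes.gene_ids, columns=list(cultivars)
        )
        for gene_id, cultivar, _kind, frac in self.records:
            retained.at[gene_id, cultivar] = frac
        return retained

    def by_cultivar(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene_id, cultivar, _kind, _frac in self.records:
            out.setdefault(cultivar, set()).add(gene_id)
        return out


# ----------------------------------------------------------------------
# Annotation + family architecture
# ----------------------------------------------------------------------
def _draw_family_sizes(rng: np.random.Generator, params: SimParams) -> list[int]:
    target = int(rng.binomial(params.n_genes, 1.0 - params.singleton_fraction))
    sizes_avail = np.array(sorted(params.family_size_weights))
    weights = np.array([params.family_size_weights[s] for s in sizes_avail])
    weights = weights / weights.sum()
    sizes: list[int] = []
    total = 0
    while total + 2 <= target:
        s = int(rng.choice(sizes_avail, p=weights))
        if total + s > target:
            s = target - total
            if s < 2:
                break
        sizes.append(s)
        total += s
    return sizes


def generate_annotation(params: SimParams) -> tuple[GeneTable, FamilyTruth]:
    """Place genes on scaffolds and plant the multi-copy family structure.

    Multi-copy families are placed as tandem runs (consecutive positional
    ranks on one scaffold) with probability ``p_tandem``, otherwise their
    members are scattered with at least nine intervening gene slots so that
    scattered families never form spurious positional clusters.
    """
    params.validate()
    rng = params._streams()["annotation"]
    n = params.n_genes
    per_scaffold = np.full(params.n_scaffolds, n // params.n_scaffolds)
    per_scaffold[: n % params.n_scaffolds] += 1

    sizes = _draw_family_sizes(rng, params)
    if sizes and max(sizes) > per_scaffold.max():
        raise ValueError(
            f"n_genes={n} over {params.n_scaffolds} scaffolds cannot host a "
            f"tandem family of {max(sizes)} genes"
        )
    if sum(sizes) > n:
        raise ValueError("family architecture requires more genes than n_genes")

    # slot bookkeeping: (scaffold index, rank) -> family assignment or None
    free: list[np.ndarray] = [np.ones(k, dtype=bool) for k in per_scaffold]
    assignment: list[np.ndarray] = [np.full(k, -1, dtype=np.int64) for k in per_scaffold]

    order = np.argsort(sizes)[::-1]  # place large families first
    tandem_flags: dict[int, bool] = {}
    for fam_idx in order:
        k = sizes[fam_idx]
        tandem = bool(rng.random() < params.p_tandem)
        tandem_flags[fam_idx] = tandem
        if tandem:
            _place_tandem(rng, fam_idx, k, free, assignment)
        else:
            _place_scattered(rng, fam_idx, k, free, assignment)

    # name genes in genome order, collect family membership
    records = []
    fam_members: dict[int, list[str]] = {i: [] for i in range(len(sizes))}
    width = max(5, len(str(n)))
    gene_no = 0
    for s_idx, n_s in enumerate(per_scaffold):
        scaffold = f"scaffold{s_idx + 1:04d}"
        pos = 0
        gap = rng.exponential(params.mean_intergenic, size=n_s).astype(np.int64) + 50
        length = np.maximum(
            200, rng.gamma(2.0, params.mean_gene_len / 2.0, size=n_s)
        ).astype(np.int64)
        strand = rng.choice(np.array(["+", "-"]), size=n_s)
        for rank in range(n_s):
            start = pos + int(gap[rank])
            end = start + int(length[rank])
            pos = end
            gene_id = f"g{gene_no:0{width}d}"
            gene_no += 1
            records.append((gene_id, scaffold, start, end, str(strand[rank])))
            fam = assignment[s_idx][rank]
            if fam >= 0:
                fam_members[int(fam)].append(gene_id)

    genes = GeneTable(records)
    members = {}
    tandem = {}
    for fam_idx, mem in fam_members.items():
        if not mem:
            continue
        fam_id = f"F_{min(mem)}"
        members[fam_id] = sorted(mem)
        tandem[fam_id] = tandem_flags[fam_idx]
    return genes, FamilyTruth(members=members, tandem=tandem)


def _free_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of free slots."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b] - idx[a] + 1)) for a, b in zip(starts, ends)]


def _place_tandem(rng, fam_idx, k, free, assignment) -> None:
    # enumerate every admissible run start across scaffolds, pick one uniformly
    choices = []  # (scaffold, run start, number of admissible offsets)
    total = 0
    for s_idx, mask in enumerate(free):
        for start, length in _free_runs(mask):
            if length >= k:
                choices.append((s_idx, start, length - k + 1))
                total += length - k + 1
    if total == 0:
        raise ValueError(
            f"no room to place a tandem family of {k} genes; "
            "increase n_genes or reduce family sizes"
        )
    r = int(rng.integers(total))
    for s_idx, start, n_off in choices:
        if r < n_off:
            start += r
            break
        r -= n_off
    free[s_idx][start : start + k] = False
    assignment[s_idx][start : start + k] = fam_idx


_SCATTER_MIN_GAP = 10  # rank separation guaranteeing >= 9 intervening slots


def _place_scattered(rng, fam_idx, k, free, assignment) -> None:
    sizes = np.array([m.size for m in free])
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    n_slots = int(offsets[-1])
    chosen: dict[int, list[int]] = {}
    placed = 0
    attempts = 0
    max_attempts = 500 * k + 1000
    while placed < k:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("not enough free gene slots for family placement")
        slot = int(rng.integers(n_slots))
        s_idx = int(np.searchsorted(offsets, slot, side="right") - 1)
        rank = slot - int(offsets[s_idx])
        if not free[s_idx][rank]:
            continue
        near = any(
            abs(rank - r) < _SCATTER_MIN_GAP for r in chosen.get(s_idx, ())
        )
        if near and attempts < 200 * k:
            continue
        free[s_idx][rank] = False
        assignment[s_idx][rank] = fam_idx
        chosen.setdefault(s_idx, []).append(rank)
        placed += 1


# ----------------------------------------------------------------------
# Deletion truth
# ----------------------------------------------------------------------
def generate_pav_truth(
    genes: GeneTable, families: FamilyTruth, params: SimParams
) -> DeletionTruth:
    """Plant per-cultivar deletions with family/cluster enrichment.

    Each (gene, non-reference cultivar) pair is deleted with probability
    ``base_del_rate``, multiplied by ``multi_copy_multiplier`` for genes in
    families and further by ``cluster_multiplier`` for genes in tandem-placed
    families. A deletion extends over a run of rank-adjacent genes with
    probability ``segment_del_prob`` (geometric run length); run deletions
    are full, isolated deletions are partial with probability
    ``partial_del_prob`` (retained fraction ~ Uniform(0.2, 0.8)).
    """
    params.validate()
    rng = params._streams()["truth"]
    multi = families.multi_copy_genes
    clustered = families.clustered_genes
    df = genes.df
    gene_ids = np.array(genes.gene_ids)
    mult = np.ones(len(gene_ids))
    mult[np.isin(gene_ids, list(multi))] *= params.multi_copy_multiplier
    mult[np.isin(gene_ids, list(clustered))] *= params.cluster_multiplier
    p = np.minimum(1.0, params.base_del_rate * mult)

    # genome order arrays for run extension
    order = {g: i for i, g in enumerate(gene_ids)}
    scaffold_arr = df["scaffold"].to_numpy()

    records: list[tuple[str, str, str, float]] = []
    for cultivar in params.cultivars:
        if cultivar == params.reference:
            continue
        seeds = np.flatnonzero(rng.random(len(gene_ids)) < p)
        deleted: set[int] = set()
        for idx in seeds:
            if idx in deleted:
                continue
            if params.segment_del_prob > 0 and rng.random() < params.segment_del_prob:
                run_len = int(rng.geometric(1.0 / params.segment_run_mean))
                run = [idx]
                for j in range(idx + 1, min(idx + run_len, len(gene_ids))):
                    if scaffold_arr[j] != scaffold_arr[idx]:
                        break
                    run.append(j)
                for j in run:
                    if j not in deleted:
                        deleted.add(j)
                        records.append((gene_ids[j], cultivar, "full", 0.0))
            else:
                deleted.add(idx)
                if rng.random() < params.partial_del_prob:
                    frac = float(rng.uniform(0.2, 0.8))
                    records.append((gene_ids[idx], cultivar, "partial", frac))
                else:
                    records.append((gene_ids[idx], cultivar, "full", 0.0))
    records.sort(key=lambda r: (r[1], order[r[0]]))
    return DeletionTruth(records=records)


# ----------------------------------------------------------------------
# Read-count and breadth simulation
# ----------------------------------------------------------------------
def simulate_counts(
    genes: GeneTable, truth: DeletionTruth, params: SimParams
) -> tuple[CountMatrix, BreadthMatrix]:
    """Draw per-gene read counts and breadth from the planted truth.

    The expected count of a present gene is
    ``depth * (len + read_len) / read_len`` (reads whose start falls within
    one read length upstream of the gene still overlap it), scaled by the
    retained fraction for deleted genes, plus
    ``background_mismap_rate * deleted_kb`` of mis-mapped background. Counts
    are Poisson, or gamma-Poisson (negative binomial) when
    ``overdispersion > 0``. Breadth equals the retained fraction exactly at
    the endpoints 0 and 1 (deep coverage saturates breadth) and gets Beta
    noise for partial deletions. Library sizes are gene-count column sums
    plus a simulated intergenic read total.
    """
    params.validate()
    rng = params._streams()["counts"]
    cultivars = list(params.cultivars)
    retained = truth.retained_matrix(genes, cultivars)
    lengths = genes.lengths().to_numpy(dtype=float)[:, None]
    ret = retained.to_numpy()

    depth = np.array([params.depth_of(c) for c in cultivars])[None, :]
    lam = depth * (lengths + params.read_len) / params.read_len * ret
    lam += params.background_mismap_rate * lengths / 1000.0 * (1.0 - ret)

    if params.overdispersion > 0:
        d = params.overdispersion
        lam = lam * rng.gamma(shape=1.0 / d, scale=d, size=lam.shape)
    counts = rng.poisson(lam)

    breadth = ret.copy()
    partial = (ret > 0) & (ret < 1)
    if partial.any():
        conc = 200.0
        r = ret[partial]
        breadth[partial] = np.clip(
            rng.beta(r * conc, (1.0 - r) * conc), 0.0, 1.0
        )

    # intergenic reads close the gap between gene-count sums and library size
    span = genes.df.groupby("scaffold")["end"].max().sum()
    intergenic_bp = max(0, int(span) - int(genes.lengths().sum()))
    inter = rng.poisson(depth[0] * intergenic_bp / params.read_len)
    libs = counts.sum(axis=0) + inter

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes.gene_ids, columns=cultivars),
        pd.Series(libs, index=cultivars),
    )
    bm = BreadthMatrix(
        pd.DataFrame(breadth, index=genes.gene_ids, columns=cultivars)
    )
    return cm, bm


# ----------------------------------------------------------------------
# Homology hits
# ----------------------------------------------------------------------
def emit_homology_hits(
    families: FamilyTruth,
    genes: GeneTable,
    seed: int,
    n_decoys: int | None = None,
) -> pd.DataFrame:
    """Emit reciprocal 12-column tabular hits for every intra-family pair.

    Real hits carry identity ~ Uniform(69, 100), mutual coverage ~
    Uniform(0.5, 1.0) and e-value <= 1e-20. Decoy hits (default: one per
    family) are built to fail the downstream filters, through either a weak
    e-value (> 1e-20) or mutual coverage <= 0.40.
    """
    rng = np.random.default_rng(seed)
    lengths = genes.lengths()
    rows = []
    gene_fam = {g: f for f, mem in families.members.items() for g in mem}

    for fam_id in sorted(families.members):
        mem = families.members[fam_id]
        for q in mem:
            for s in mem:
                if q == s:
                    continue
                rows.append(_hit_row(rng, q, s, lengths, real=True))

    if n_decoys is None:
        n_decoys = max(1, len(families.members))
    all_genes = genes.gene_ids
    made = 0
    while made < n_decoys and len(all_genes) >= 2:
        q, s = (all_genes[int(i)] for i in rng.integers(len(all_genes), size=2))
        if q == s:
            continue
        if gene_fam.get(q) is not None and gene_fam.get(q) == gene_fam.get(s):
            continue  # never shadow a real intra-family pair
        rows.append(_hit_row(rng, q, s, lengths, real=False))
        made += 1

    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _hit_row(rng, q: str, s: str, lengths: pd.Series, real: bool) -> list:
    qlen, slen = int(lengths[q]), int(lengths[s])
    if real:
        cov = rng.uniform(0.5, 1.0)
        evalue = float(10.0 ** -rng.uniform(25.0, 180.0))
        qend = max(1, math.ceil(cov * qlen))
        send = max(1, math.ceil(cov * slen))
    elif rng.random() < 0.5:  # weak e-value decoy
        cov = rng.uniform(0.5, 1.0)
        evalue = float(10.0 ** -rng.uniform(2.0, 19.0))
        qend = max(1, math.ceil(cov * qlen))
        send = max(1, math.ceil(cov * slen))
    else:  # short-alignment decoy: both coverages <= 0.40
        cov = rng.uniform(0.05, 0.40)
        evalue = float(10.0 ** -rng.uniform(25.0, 180.0))
        qend = max(1, min(int(cov * qlen), int(0.40 * qlen)))
        send = max(1, min(int(cov * slen), int(0.40 * slen)))
    pident = float(rng.uniform(69.0, 100.0))
    length = max(qend, send)
    mismatch = int(round(length * (1.0 - pident / 100.0)))
    bitscore = round(2.0 * length * pident / 100.0, 1)
    return [q, s, round(pident, 2), length, mismatch, 0, 1, qend, 1, send, evalue, bitscore]


def write_hits(hits: pd.DataFrame, path) -> None:
    """Write hits in headerless 12-column tabular format."""
    hits.to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# Truth serialization + one-call cohort
# ----------------------------------------------------------------------
def write_truth(path, families: FamilyTruth, deletions: DeletionTruth) -> None:
    payload = {
        "families": {
            fam: {"members": mem, "tandem": families.tandem[fam]}
            for fam, mem in sorted(families.members.items())
        },
        "deletions": [
            {"gene_id": g, "cultivar": c, "kind": k, "retained_fraction": f}
            for g, c, k, f in deletions.records
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> tuple[FamilyTruth, DeletionTruth]:
    with open(path) as fh:
        payload = json.load(fh)
    families = FamilyTruth(
        members={f: d["members"] for f, d in payload["families"].items()},
        tandem={f: d["tandem"] for f, d in payload["families"].items()},
    )
    deletions = DeletionTruth(
        records=[
            (d["gene_id"], d["cultivar"], d["kind"], d["retained_fraction"])
            for d in payload["deletions"]
        ]
    )
    return families, deletions


@dataclass
class Cohort:
    """In-memory synthetic cohort: annotation, truth, matrices, hits."""

    params: SimParams
    genes: GeneTable
    families: FamilyTruth
    deletions: DeletionTruth
    counts: CountMatrix
    breadth: BreadthMatrix
    hits: pd.DataFrame


def simulate_cohort(params: SimParams) -> Cohort:
    """Run the full generator pipeline with the parameter set's master seed."""
    genes, families = generate_annotation(params)
    deletions = generate_pav_truth(genes, families, params)
    counts, breadth = simulate_counts(genes, deletions, params)
    hits_seed = int(np.random.SeedSequence(params.seed).spawn(4)[3].generate_state(1)[0] % (2**31))
    hits = emit_homology_hits(families, genes, seed=hits_seed)
    return Cohort(params, genes, families, deletions, counts, breadth, hits)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write GFF3, count/breadth TSVs, hits TSV and truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "breadth": outdir / "breadth.tsv",
        "hits": outdir / "hits.tsv",
        "truth": outdir / "truth.json",
        "params": outdir / "params.json",
    }
    cohort.genes.to_gff3(paths["gff3"])
    cohort.counts.to_tsv(paths["counts"])
    cohort.breadth.to_tsv(paths["breadth"])
    write_hits(cohort.hits, paths["hits"])
    write_truth(paths["truth"], cohort.families, cohort.deletions)
    with open(paths["params"], "w") as fh:
        json.dump(
            dataclasses.asdict(cohort.params), fh, indent=1, default=str
        )
    return paths
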