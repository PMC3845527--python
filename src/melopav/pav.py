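"""Presence/absence-variation calling from per-gene read counts.

Two candidate screens are applied to the gene x cultivar count data:

* **ratio screen** — a gene is a candidate when some ordered cultivar pair
  has a normalized count ratio below 0.5 (equivalently above 2.0 for the
  reversed pair);
* **absolute screen** — a candidate has fewer than 6 raw reads in at least
  one cultivar and more than 29 in at least another.

Candidates where every cultivar has fewer than 10 reads are discarded
(nothing can be said about a gene no cultivar covers). The visual review
of mapping patterns that such studies traditionally perform is replaced
by a deterministic rule on relative normalized depth and, when a breadth
matrix is available, breadth-of-coverage windows that separate full from
partial absence. All inequalities in the screens are strict.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CountMatrix

logger = logging.getLogger(__name__)

PRESENT, PARTIAL, ABSENT = "present", "partial", "absent"


@dataclass
class Thresholds:
    """All screening and review constants, with the conventional defaults."""

    ratio_low: float = 0.5
    ratio_high: float = 2.0
    abs_low: int = 6  # candidate needs a cultivar with strictly fewer reads
    abs_high: int = 29  # ... and another with strictly more
    min_support: int = 10  # discard if below in ALL cultivars
    absence_rel: float = 0.05  # absent if norm <= absence_rel * cohort max
    breadth_absent: float = 0.10
    breadth_partial: float = 0.80

    def __post_init__(self):
        if not 0 < self.ratio_low < 1 < self.ratio_high:
            raise ValueError("need 0 < ratio_low < 1 < ratio_high")
        if self.abs_low > self.abs_high:
            raise ValueError("abs_low must be <= abs_high")
        if not 0 <= self.breadth_absent < self.breadth_partial <= 1:
            raise ValueError("need 0 <= breadth_absent < breadth_partial <= 1")


# ----------------------------------------------------------------------
# Screens
# ----------------------------------------------------------------------
def screen_ratio(
    norm: pd.DataFrame,
    th: Thresholds | None = None,
    zero_support: float | None = None,
) -> set[str]:
    """Genes with an extreme normalized-count ratio between some cultivar pair.

    A gene is a candidate iff for some ordered pair (a, b):
    ``norm[b] > 0 and norm[a]/norm[b] < ratio_low`` (the mirrored ``> ratio_high``
    screen selects the same genes over ordered pairs), or ``norm[b] == 0`` and
    ``norm[a] >= zero_support`` — the zero-denominator rule, which demands real
    coverage on the other side of an all-or-nothing contrast.
    ``zero_support`` defaults to ``min_support`` in normalized units. Over
    ordered pairs this collapses to ``min/max < ratio_low`` whenever the max
    is positive, since a zero numerator always yields ratio 0.
    """
    th = th or Thresholds()
    if norm.shape[1] < 2:
        raise ValueError("ratio screen needs at least two cultivars")
    if zero_support is None:
        zero_support = float(th.min_support)
    mn = norm.min(axis=1)
    mx = norm.max(axis=1)
    pair_case = (mx > 0) & (mn < th.ratio_low * mx)
    zero_denominator_case = (mn == 0) & (mx >= zero_support)
    return set(norm.index[pair_case | zero_denominator_case])


def screen_absolute(raw: pd.DataFrame | CountMatrix, th: Thresholds | None = None) -> set[str]:
    """Genes with < ``abs_low`` raw reads in one cultivar and > ``abs_high`` in another."""
    th = th or Thresholds()
    counts = raw.counts if isinstance(raw, CountMatrix) else raw
    cand = (counts.min(axis=1) < th.abs_low) & (counts.max(axis=1) > th.abs_high)
    return set(counts.index[cand])


def filter_low_support(
    raw: pd.DataFrame | CountMatrix,
    candidates: set[str],
    th: Thresholds | None = None,
) -> tuple[set[str], set[str]]:
    """Split candidates into (retained, discarded): discarded genes have
    fewer than ``min_support`` reads in *every* cultivar."""
    th = th or Thresholds()
    counts = raw.counts if isinstance(raw, CountMatrix) else raw
    sub = counts.loc[sorted(candidates)]
    low_all = sub.max(axis=1) < th.min_support
    discarded = set(sub.index[low_all])
    return candidates - discarded, discarded


def merge_candidates(
    ratio_set: set[str],
    absolute_set: set[str],
    manual_additions: set[str] | None = None,
) -> dict[str, set[str]]:
    """Union of screen outputs with per-gene screen provenance tags."""
    provenance: dict[str, set[str]] = {}
    for gene in ratio_set:
        provenance.setdefault(gene, set()).add("ratio")
    for gene in absolute_set:
        provenance.setdefault(gene, set()).add("absolute")
    for gene in manual_additions or ():
        provenance.setdefault(gene, set()).add("manual")
    return provenance


def read_manual_additions(path) -> set[str]:
    """One gene_id per line; blank lines and # comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


# ----------------------------------------------------------------------
# Absence review
# ----------------------------------------------------------------------
def assign_absences(
    candidates: dict[str, set[str]] | set[str],
    norm: pd.DataFrame,
    breadth: pd.DataFrame | None,
    th: Thresholds | None = None,
    reference_cultivar: str | None = None,
) -> pd.DataFrame:
    """Per-cultivar status for each candidate gene.

    A cultivar is called *absent* when its normalized count is at most
    ``absence_rel`` times the cohort maximum for the gene and, if breadth is
    available, breadth is at most ``breadth_absent``; *partial* when breadth
    falls strictly between ``breadth_absent`` and ``breadth_partial``.
    Candidate genes with no absent or partial cultivar are dropped. Returns a
    tidy frame of (gene_id, cultivar, status, screens, norm, breadth,
    artifact_flag) rows covering all cultivars of the surviving genes.
    """
    th = th or Thresholds()
    if isinstance(candidates, set):
        candidates = {g: set() for g in candidates}
    if breadth is None:
        logger.warning("no breadth matrix: partial-absence calling disabled")
    rows = []
    for gene in sorted(candidates):
        gnorm = norm.loc[gene]
        gmax = float(gnorm.max())
        statuses = {}
        for cultivar in norm.columns:
            b = None if breadth is None else float(breadth.at[gene, cultivar])
            low_depth = float(gnorm[cultivar]) <= th.absence_rel * gmax
            if low_depth and (b is None or b <= th.breadth_absent):
                statuses[cultivar] = ABSENT
            elif b is not None and th.breadth_absent < b < th.breadth_partial:
                statuses[cultivar] = PARTIAL
            else:
                statuses[cultivar] = PRESENT
        if not any(s != PRESENT for s in statuses.values()):
            continue
        screens = ",".join(sorted(candidates[gene]))
        for cultivar in norm.columns:
            b = None if breadth is None else float(breadth.at[gene, cultivar])
            rows.append(
                (gene, cultivar, statuses[cultivar], screens,
                 float(gnorm[cultivar]), b, False)
            )
    calls = pd.DataFrame(
        rows,
        columns=["gene_id", "cultivar", "status", "screens", "norm", "breadth",
                 "artifact_flag"],
    )
    if reference_cultivar is not None and len(calls):
        calls = flag_reference_artifacts(calls, reference_cultivar)
    return calls


def flag_reference_artifacts(
    calls: pd.DataFrame,
    reference_cultivar: str,
    parents: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Flag absences called in the reference cultivar as mapping artifacts.

    When the reference's own reads are mapped back to its assembly, no true
    absence is possible; such calls are kept but flagged and excluded from
    per-cultivar averages. If the reference line's two parents are given,
    reference absences with both parents present additionally get a
    ``parent-inconsistent`` tag in the screens column (a clear false
    positive: every reference segment derives from one of the parents).
    """
    calls = calls.copy()
    is_event = calls["status"].isin([ABSENT, PARTIAL])
    ref_event = is_event & (calls["cultivar"] == reference_cultivar)
    calls.loc[ref_event, "artifact_flag"] = True
    if parents is not None:
        p1, p2 = parents
        status = calls.pivot_table(
            index="gene_id", columns="cultivar", values="status", aggfunc="first"
        )
        for gene in calls.loc[ref_event, "gene_id"].unique():
            if gene not in status.index:
                continue
            row = status.loc[gene]
            if row.get(p1) == PRESENT and row.get(p2) == PRESENT:
                mask = ref_event & (calls["gene_id"] == gene)
                calls.loc[mask, "screens"] = (
                    calls.loc[mask, "screens"]
                    .str.split(",")
                    .apply(lambda s: ",".join(sorted(set(filter(None, s)) | {"parent-inconsistent"})))
                )
    return calls


def call_pav(
    counts: CountMatrix,
    breadth: pd.DataFrame | None = None,
    th: Thresholds | None = None,
    reference_cultivar: str | None = None,
    manual_additions: set[str] | None = None,
    parents: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Full calling chain: screens -> low-support filter -> absence review.

    Convenience wrapper over :func:`screen_ratio`, :func:`screen_absolute`,
    :func:`filter_low_support`, :func:`merge_candidates`,
    :func:`assign_absences` and :func:`flag_reference_artifacts` with the
    default thresholds.
    """
    th = th or Thresholds()
    norm = counts.normalize()
    merged = merge_candidates(
        screen_ratio(norm, th), screen_absolute(counts, th), manual_additions
    )
    retained, _discarded = filter_low_support(counts, set(merged), th)
    calls = assign_absences(
        {g: merged[g] for g in retained}, norm, breadth, th, reference_cultivar
    )
    if parents is not None and reference_cultivar is not None and len(calls):
        calls = flag_reference_artifacts(calls, reference_cultivar, parents)
    return calls


# ----------------------------------------------------------------------
# Summary
# ----------------------------------------------------------------------
@dataclass
class PavSummary:
    """Cohort-level PAV tallies."""

    n_pav_genes: int
    n_events: int
    pav_fraction_of_complement: float | None
    genes_by_n_absent_cultivars: dict[int, int]
    events_per_cultivar: dict[str, int]
    event_share_per_cultivar: dict[str, float]  # % of all events
    n_reference_artifacts: int
    mean_absent_per_cultivar: float  # excludes flagged reference events
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes_by_n_absent_cultivars"] = {
            str(k): v for k, v in self.genes_by_n_absent_cultivars.items()
        }
        return d


def summarize(
    calls: pd.DataFrame,
    n_genes_universe: int | None = None,
    reference_cultivar: str | None = None,
) -> PavSummary:
    """Tally PAV genes, events, per-cultivar shares and the absence histogram.

    An *event* is one (gene, cultivar) absent or partial call; a gene absent
    in k cultivars contributes k events. Reference-cultivar artifact events
    are counted in the totals (they are observations) but excluded from the
    mean number of absent genes per cultivar.
    """
    events = calls[calls["status"].isin([ABSENT, PARTIAL])]
    n_events = len(events)
    per_gene = events.groupby("gene_id").size()
    hist = per_gene.value_counts().sort_index()
    per_cultivar = events.groupby("cultivar").size()
    n_art = int(events["artifact_flag"].sum())
    non_ref = events[~events["artifact_flag"]]
    n_cultivars_non_ref = max(
        1, non_ref["cultivar"].nunique() if len(non_ref) else 1
    )
    return PavSummary(
        n_pav_genes=int(per_gene.size),
        n_events=int(n_events),
        pav_fraction_of_complement=(
            None
            if n_genes_universe is None
            else round(100.0 * per_gene.size / n_genes_universe, 1)
        ),
        genes_by_n_absent_cultivars={int(k): int(v) for k, v in hist.items()},
        events_per_cultivar={str(c): int(v) for c, v in per_cultivar.items()},
        event_share_per_cultivar={
            str(c): round(100.0 * v / n_events, 1) for c, v in per_cultivar.items()
        }
        if n_events
        else {},
        n_reference_artifacts=n_art,
        mean_absent_per_cultivar=(
            round(len(non_ref) / n_cultivars_non_ref, 1) if len(non_ref) else 0.0
        ),
    )


# ----------------------------------------------------------------------
# Output writers
# ----------------------------------------------------------------------
def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cultivar": str})
    df["screens"] = df["screens"].fillna("")
    return df


def write_summary(summary: PavSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1)


def absent_regions_bed(calls: pd.DataFrame, genes) -> pd.DataFrame:
    """Merged runs of absent genes per cultivar as 0-based half-open BED rows.

    Consecutive (by positional rank) absent genes of one cultivar on one
    scaffold merge into a single region; partial calls are not merged in.
    """
    rows = []
    gdf = genes.df
    absent = calls[calls["status"] == ABSENT]
    for cultivar, sub in absent.groupby("cultivar"):
        marked = gdf.loc[gdf.index.intersection(sub["gene_id"])]
        for scaffold, sgenes in marked.groupby("scaffold"):
            sgenes = sgenes.sort_values("rank")
            run_start = run_end = None
            prev_rank = None
            for row in sgenes.itertuples():
                if prev_rank is not None and row.rank == prev_rank + 1:
                    run_end = row.end
                else:
                    if run_start is not None:
                        rows.append((scaffold, run_start, run_end, cultivar))
                    run_start, run_end = row.start, row.end
                prev_rank = row.rank
            if run_start is not None:
                rows.append((scaffold, run_start, run_end, cultivar))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return bed.sort_values(["chrom", "start", "name"]).reset_index(drop=True)
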