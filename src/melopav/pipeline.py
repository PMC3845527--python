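"""End-to-end pipeline: count -> call -> families -> clusters -> enrich.

A single YAML config names the inputs (annotation, counts or BAMs,
homology hits, optional breadth / manual additions / cluster overrides),
the cultivar roles and every threshold. ``run_pipeline`` executes the
stages in order, logs the candidate counts surviving each screen and
filter, and writes a machine-readable ``summary.json`` plus the per-stage
tables into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clusters as cl
from . import enrichment, families as fam, pav
from .coverage import BreadthMatrix, CountMatrix, count_matrix_from_bams
from .genes import GeneTable

logger = logging.getLogger("melopav")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    gff3: str
    counts: str | None = None  # counts TSV ...
    bams: dict[str, str] | None = None  # ... or cultivar -> BAM path
    hits: str | None = None
    breadth: str | None = None
    manual_additions: str | None = None
    cluster_overrides: str | None = None
    reference: str | None = None
    parents: tuple[str, str] | None = None
    thresholds: pav.Thresholds = field(default_factory=pav.Thresholds)
    e_max: float = 1e-20
    cov_min: float = 0.40
    max_intervening: int = 8
    min_mapq: int = 1
    outdir: str = "melopav_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = pav.Thresholds(**raw.pop("thresholds", {}))
        if "parents" in raw and raw["parents"] is not None:
            raw["parents"] = tuple(raw["parents"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=th, **raw)

    def validate(self) -> None:
        if self.counts is None and not self.bams:
            raise ConfigError("config needs either 'counts' or 'bams'")
        for label, path in [
            ("gff3", self.gff3),
            ("counts", self.counts),
            ("hits", self.hits),
            ("breadth", self.breadth),
            ("manual_additions", self.manual_additions),
            ("cluster_overrides", self.cluster_overrides),
        ]:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")
        for cultivar, path in (self.bams or {}).items():
            if not Path(path).exists():
                raise ConfigError(f"BAM for {cultivar!r} not found: {path}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory.

    Fails fast with a stage-named message; partial outputs are marked by an
    ``INCOMPLETE`` sentinel file that is removed on success.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sentinel = outdir / "INCOMPLETE"
    sentinel.touch()
    logging.basicConfig(level=config.log_level)
    stage = "load-annotation"
    try:
        genes = GeneTable.from_gff3(config.gff3)
        logger.info("annotation: %d genes on %d scaffolds", len(genes), len(genes.scaffolds))

        stage = "count"
        if config.counts is not None:
            counts = CountMatrix.from_tsv(config.counts)
        else:
            counts = count_matrix_from_bams(config.bams, genes, min_mapq=config.min_mapq)
        breadth = (
            BreadthMatrix.from_tsv(config.breadth).breadth
            if config.breadth
            else None
        )
        _check_cultivars(config, counts)

        stage = "call"
        th = config.thresholds
        norm = counts.normalize()
        ratio_set = pav.screen_ratio(norm, th)
        logger.info("ratio screen: %d candidate genes", len(ratio_set))
        abs_set = pav.screen_absolute(counts, th)
        logger.info("absolute screen: %d candidate genes", len(abs_set))
        manual = (
            pav.read_manual_additions(config.manual_additions)
            if config.manual_additions
            else set()
        )
        merged = pav.merge_candidates(ratio_set, abs_set, manual)
        retained, discarded = pav.filter_low_support(counts, set(merged), th)
        logger.info(
            "candidates: %d merged, %d discarded by the <%d-reads-everywhere filter",
            len(merged), len(discarded), th.min_support,
        )
        candidates = {g: merged[g] for g in retained}
        calls = pav.assign_absences(
            candidates, norm, breadth, th, reference_cultivar=config.reference
        )
        if config.parents and config.reference:
            calls = pav.flag_reference_artifacts(calls, config.reference, config.parents)
        summary = pav.summarize(calls, n_genes_universe=len(genes),
                                reference_cultivar=config.reference)
        logger.info("final PAV list: %d genes, %d events", summary.n_pav_genes, summary.n_events)
        pav.write_calls(calls, outdir / "calls.tsv")
        bed = pav.absent_regions_bed(calls, genes)
        bed.to_csv(outdir / "pav_regions.bed", sep="\t", index=False, header=False)

        pav_genes = set(calls.loc[calls["status"] != pav.PRESENT, "gene_id"])
        summary_doc = {"pav": summary.to_dict(), "thresholds": dataclasses.asdict(th)}

        if config.hits:
            stage = "families"
            hits = fam.read_hits(config.hits)
            edges = fam.filter_hits(hits, genes.lengths(), config.e_max, config.cov_min)
            family_map, singletons = fam.build_families(edges, genes.gene_ids)
            fam.write_families(family_map, singletons, outdir)
            fdist = fam.family_size_distribution(family_map, len(genes))
            logger.info("families: %d multi-copy families, %d singletons",
                        len(family_map), len(singletons))

            stage = "clusters"
            cluster_list = cl.detect_clusters(family_map, genes, config.max_intervening)
            if config.cluster_overrides:
                cluster_list = cl.override_membership(
                    cluster_list, config.cluster_overrides, genes, family_map
                )
            cl.write_clusters(cluster_list, genes, outdir)
            cdist = cl.cluster_size_distribution(cluster_list)
            logger.info("clusters: %d tandem clusters", len(cluster_list))

            stage = "enrich"
            universe = set(genes.gene_ids)
            multi = {g for mem in family_map.values() for g in mem}
            clustered = cl.clustered_genes(cluster_list)
            summary_doc["families"] = {
                "n_families": fdist.attrs["n_families"],
                "n_multi_copy_genes": fdist.attrs["n_multi_copy_genes"],
                "singleton_fraction_pct": fdist.attrs["singleton_fraction_pct"],
                "size_table": fdist.reset_index().to_dict(orient="records"),
                "band_share_of_multi_genes_pct": fdist.attrs["band_share_of_multi_genes_pct"],
            }
            summary_doc["clusters"] = {
                "n_clusters": cdist.attrs["n_clusters"],
                "n_clustered_genes": cdist.attrs["n_clustered_genes"],
                "share_genes_in_clusters_ge5_pct": cdist.attrs["share_genes_in_clusters_ge5_pct"],
                "size_table": cdist.reset_index().to_dict(orient="records"),
            }
            summary_doc["enrichment"] = {}
            for name, attr in (("multi_copy", multi), ("clustered", clustered)):
                try:
                    summary_doc["enrichment"][name] = enrichment.crosstab(
                        pav_genes, attr, universe
                    ).to_dict()
                except ValueError as exc:  # degenerate margin
                    summary_doc["enrichment"][name] = {"error": str(exc)}

        stage = "write-summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary_doc, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    sentinel.unlink()
    return outdir


def _check_cultivars(config: PipelineConfig, counts: CountMatrix) -> None:
    names = set(counts.cultivars)
    roles = [config.reference, *(config.parents or ())]
    for role in roles:
        if role is not None and role not in names:
            raise ConfigError(
                f"cultivar {role!r} from config not found in count matrix "
                f"columns {sorted(names)}"
            )


# ----------------------------------------------------------------------
# Report rendering
# ----------------------------------------------------------------------
def render_report(summary: dict) -> str:
    """Markdown report of a pipeline summary; pure formatting, every number
    comes straight from the summary document."""
    lines = ["# PAV analysis report", ""]
    p = summary.get("pav", {})
    lines += ["## Presence/absence calls", ""]
    lines.append(f"- PAV genes: {p.get('n_pav_genes', 0)}")
    if p.get("pav_fraction_of_complement") is not None:
        lines.append(
            f"- Fraction of the annotated gene complement: {p['pav_fraction_of_complement']}%"
        )
    lines.append(f"- PAV events (gene x cultivar absences): {p.get('n_events', 0)}")
    lines.append(f"- Reference-cultivar artifact events: {p.get('n_reference_artifacts', 0)}")
    hist = p.get("genes_by_n_absent_cultivars", {})
    if hist:
        lines += ["", "| absent in # cultivars | genes |", "|---|---|"]
        for k in sorted(hist, key=int):
            lines.append(f"| {k} | {hist[k]} |")
    shares = p.get("event_share_per_cultivar", {})
    if shares:
        lines += ["", "| cultivar | events | share |", "|---|---|---|"]
        counts = p.get("events_per_cultivar", {})
        for c in sorted(shares):
            lines.append(f"| {c} | {counts.get(c, 0)} | {shares[c]}% |")
    for key, title, unit in (
        ("families", "Gene families", "family_size"),
        ("clusters", "Tandem clusters", "cluster_size"),
    ):
        block = summary.get(key)
        if not block:
            continue
        lines += ["", f"## {title}", ""]
        for k, v in block.items():
            if k == "size_table":
                continue
            lines.append(f"- {k}: {v}")
        table = block.get("size_table") or []
        if table:
            cols = list(table[0])
            lines += ["", "| " + " | ".join(cols) + " |",
                      "|" + "---|" * len(cols)]
            for row in table:
                lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    enr = summary.get("enrichment")
    if enr:
        lines += ["", "## Enrichment", ""]
        for name, res in enr.items():
            lines.append(f"### {name}")
            if "error" in res:
                lines.append(f"- not testable: {res['error']}")
                continue
            lines.append(f"- table (attr +/- x PAV +/-): {res['table']}")
            corr = "Yates-corrected" if res.get("yates") else "uncorrected"
            lines.append(f"- chi-square ({corr}, df=1): {res['chi2']:.1f}, p = {res['p_value']:.3g}")
            lines.append(
                f"- PAV rate: {res['pav_rate_in_attr']}% in attribute+ vs "
                f"{res['pav_rate_in_nonattr']}% in attribute- "
                f"(rate ratio {res['rate_ratio']:.2f})"
            )
            lines.append("")
    return "\n".join(lines) + "\n"
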