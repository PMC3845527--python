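"""Run the whole pipeline on generated files, the way the CLI does.

Writes a synthetic cohort to disk, builds a pipeline configuration, runs
count-loading -> calling -> families -> clusters -> enrichment, and renders
the markdown report from the resulting summary.json.
"""

import json
import tempfile
from pathlib import Path

from melopav import SimParams, simulate_cohort
from melopav.pipeline import PipelineConfig, render_report, run_pipeline
from melopav.simulate import write_cohort

workdir = Path(tempfile.mkdtemp(prefix="melopav_demo_"))
params = SimParams(n_genes=3000, n_scaffolds=8, depth_per_cultivar=13.0, seed=7)
write_cohort(simulate_cohort(params), workdir / "cohort")

config = PipelineConfig(
    gff3=str(workdir / "cohort" / "genes.gff3"),
    counts=str(workdir / "cohort" / "counts.tsv"),
    breadth=str(workdir / "cohort" / "breadth.tsv"),
    hits=str(workdir / "cohort" / "hits.tsv"),
    reference="DHL92",
    parents=("T111", "PI161375"),
    outdir=str(workdir / "run"),
)
outdir = run_pipeline(config)
summary = json.loads((outdir / "summary.json").read_text())
print(render_report(summary))
print(f"(full outputs in {outdir})")
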