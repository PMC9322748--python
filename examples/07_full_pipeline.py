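"""The whole study in one call: simulate -> preprocess -> contrast ->
select -> concordance, with a checksummed manifest.

Writes every artifact (probe/truth tables, expression matrix, QC
report, per-contrast MA and selection tables, concordance summaries,
recall, manifest) under an output directory.  The same config and
seed always produce byte-identical artifacts.
"""

import json
import tempfile
from pathlib import Path

from mahex.pipeline import RunConfig, run_pipeline
from mahex.simulate import SimConfig

outdir = Path(tempfile.mkdtemp(prefix="mahex_run_"))
config = RunConfig(
    outdir=outdir,
    sim=SimConfig(n_probesets=3_000, probes_per_set=5, de_fraction=0.01,
                  seed=19),
    gridsize=30,
    target_n=100,
)
report = run_pipeline(config)

print(report.summary[["contrast_id", "comparison", "total",
                      "pct_up", "pct_down"]].to_string(index=False))
print(f"\nconcordance over the selection intersections: "
      f"{json.dumps(report.concordance, default=str)}")
print(f"{len(report.manifest['files'])} artifacts in {outdir}")
# The summary table mirrors a per-contrast DEG report: a fixed-size
# selection per comparison with its up/down percentage split.
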