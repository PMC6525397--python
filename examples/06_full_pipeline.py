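"""Run the whole chain through the pipeline driver.

Equivalent to `roimcr run config.json -o outdir`: simulate (or load) runs,
ROI-search each, augment, resolve, screen — persisting every stage bundle
and a JSON report.
"""

import json
import tempfile
from pathlib import Path

from roimcr.cli import RunConfig, run_pipeline

config = RunConfig(
    thresh=500.0, mzerror=0.05, minroi=5, n_components=5, seed=11,
    mcp="benjamini_hochberg",
    simulate={"n_control": 3, "n_exposed": 3, "group_effect": [[3, 4.0]]},
)
outdir = Path(tempfile.mkdtemp()) / "study"
run_pipeline(config, outdir)

report = json.loads((outdir / "report.json").read_text())
print(json.dumps({k: report[k] for k in
                  ("samples", "n_rois_per_sample", "augmented_shape",
                   "n_components", "lof_percent", "evar_percent",
                   "n_significant", "biomarkers")}, indent=1))
print(f"stage bundles under {outdir}: roi/, augmented/, mcr/, biomarkers/ — "
      "all plain CSV + JSON, reloadable with roimcr.read_bundle")
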