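"""End-to-end comparison of a stiff (ePTFE) and compliant (ePU) graft case.

Generates the synthetic two-case dataset on an idealized graft-vein
anastomosis, runs the full pipeline (WSS metrics, flow disturbance, wall
mechanics, regional report) and prints the anastomotic rows.
"""

import tempfile
from pathlib import Path

import pandas as pd

from graftmetrics import make_demo, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = make_demo(Path(tmp) / "data", seed=7)
    artefacts = run_pipeline(str(cfg), Path(tmp) / "out")
    report = pd.read_csv(artefacts["report"])

anas = report[report["region"] == "anastomosis"]
table = anas.pivot(index="metric", columns="case", values="value")
print(table.to_string(float_format=lambda v: f"{v:.3f}"))

graft = report[(report["region"] == "graft") & (report["metric"] == "median strain")]
print("\ngraft-wall median strain (%):")
print(graft.pivot(index="metric", columns="case", values="value").to_string(
    float_format=lambda v: f"{v:.2f}"))

print(
    "\nThe stiff ePTFE case shows larger areas of oscillatory shear"
    " (OSI>0.25), more area above 7 Pa and stronger velocity perturbations"
    " than the compliant ePU case, whose graft wall in turn strains more."
)
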