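"""Full synthetic cohort: simulate, quantify, classify and analyze.

Runs the study-scale demo (19 patients, 60/70/120 min, two missing
120-min scans) and prints the headline statistics: time-stability of TBR
vs the decline of SUVmean, the TBR - NT-proBNP association, and the
responder / non-responder separation.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from fapitbr import run_demo

with tempfile.TemporaryDirectory() as tmp:
    run_demo(seed=1, outdir=tmp)
    metrics = pd.read_csv(Path(tmp) / "metrics.csv")
    report = json.loads((Path(tmp) / "report.json").read_text())

print(metrics.groupby("time_min")[["suvmean_bp", "suvmean_efm", "tbr_efm"]].mean().round(3))
print()
by_id = {a["analysis_id"]: a for a in report["analyses"]}
print(f"TBR time effect (mixed model)      p = {by_id['stability_tbr_efm']['p_value']:.3f}")
print(f"SUVmean(EFM) time effect           p = {by_id['stability_suvmean_efm']['p_value']:.2e}")
a = by_id["tbr_vs_log_ntprobnp_60min"]
print(f"TBR vs log NT-proBNP (60 min)      r = {a['effect']['r']:.2f}, p = {a['p_value']:.3f}")
g = by_id["responder_tbr_60min"]
print(
    f"responders {g['effect']['mean_a']:.2f} vs non-responders {g['effect']['mean_b']:.2f} "
    f"(Mann-Whitney p = {g['p_value']:.3f})"
)
print()
print("Tracer clears proportionally from blood and myocardium beyond 60 min,")
print("so absolute SUV falls with time while the blood-normalized TBR stays")
print("flat; lower baseline TBR marks patients who improve one year post-TAVI.")
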