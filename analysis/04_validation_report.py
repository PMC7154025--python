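"""Compare the calibrated twins against the synthetic experiments.

Builds the discrepancy-norm table (relative L2 / Linf for P_LV, P_Ao, Q_Ao)
and the scalar hemodynamic summaries for both presets — the same shape of
report used to validate the reference 3D simulations against the measured
rig data.

Writes results/validation_report.json and results/discrepancy_table.csv.
"""

import json
from pathlib import Path

import pandas as pd

from pulsetwin.compare import compare_twin_to_experiment
from pulsetwin.presets import get_preset
from pulsetwin.synthetic import calibrated_twin, gen_experiment

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = 1

report_all = {}
rows = []
for name in ("porcine", "pericardial"):
    preset = get_preset(name)
    twin = calibrated_twin(preset)
    ds = gen_experiment(preset, n_cycles=50, seed=SEED, twin=twin)
    report = compare_twin_to_experiment(twin.result, ds, preset.fluid)
    report_all[name] = report.to_dict()
    for sig in ("P_LV", "P_Ao", "Q_Ao"):
        rows.append({"preset": name, "signal": sig,
                     "l2_percent": report.l2[sig],
                     "linf_percent": report.linf[sig]})

df = pd.DataFrame(rows)
df.to_csv(OUT / "discrepancy_table.csv", index=False,
          float_format="%.3f")
with open(OUT / "validation_report.json", "w") as fh:
    json.dump(report_all, fh, indent=1, sort_keys=True)
print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print("\n(The published porcine L2 levels are 3.4 / 1.9 / 4.7 % for "
      "P_LV / P_Ao / Q_Ao; the twin-vs-synthetic-experiment discrepancies "
      "sit at or below these because the generator is built on the twin.)")
print("wrote results/validation_report.json, results/discrepancy_table.csv")
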