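"""Fit leaflet constitutive parameters to synthetic biaxial protocols.

Generates noise-free and 2%-noise biaxial stress-stretch tables from the two
published constitutive sets, refits them, and tabulates the recovered
parameters and residuals.  This validates that the equibiaxial + two
strip-biaxial protocol design identifies the model before the constants are
used anywhere downstream.

Writes results/material_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pulsetwin.constitutive import MaterialParams, fit_material_params
from pulsetwin.presets import FIBER_ANGLES, MATERIALS
from pulsetwin.synthetic import gen_biaxial_dataset

OUT = Path("results")
OUT.mkdir(exist_ok=True)

rows = []
for name, truth in MATERIALS.items():
    angle = FIBER_ANGLES[name]
    init = MaterialParams(c10=1.0, c01=5.0, k1=500.0, k2=1.0,
                          kappa=truth.kappa)
    for noise in (0.0, 0.02):
        data = gen_biaxial_dataset(truth, noise_cv=noise, seed=42,
                                   fiber_angle=angle)
        fit = fit_material_params(data, init, fixed_kappa=truth.kappa,
                                  fiber_angle=angle, n_starts=3)
        for pname in ("c10", "c01", "k1", "k2"):
            tru, est = getattr(truth, pname), getattr(fit.params, pname)
            rows.append({
                "material": name, "noise_cv": noise, "parameter": pname,
                "truth": tru, "estimate": est,
                "rel_error": abs(est - tru) / abs(tru) if tru else np.nan,
                "rms_residual_kPa": fit.residual, "r_squared": fit.r_squared,
            })

df = pd.DataFrame(rows)
df.to_csv(OUT / "material_fits.csv", index=False)
print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
worst = df[df.noise_cv == 0.0].rel_error.max()
print(f"\nNoise-free recovery: worst relative error {worst:.2e} "
      "(protocol design identifies every constant).")
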