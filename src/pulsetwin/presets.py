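"""Tabulated parameter presets for the two bioprosthetic valves.

All values are the published constants of the reference pulse-duplicator
study: constitutive sets fitted to glutaraldehyde-fixed porcine aortic valve
and bovine pericardial biaxial data, the upstream/downstream circuit elements,
the working-fluid properties, and the experimental hemodynamic summaries
(stroke volume, maximum forward-flow pressure difference, peak Reynolds
number) that the synthetic-experiment generator targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import FluidProperties, RCRWindkessel
from .constitutive import MaterialParams
from .units import cp_to_poise

__all__ = [
    "TEST_SECTION_DIAMETER_CM",
    "SALINE",
    "BLOOD_ANALOGUE",
    "MATERIALS",
    "ExperimentPreset",
    "PRESETS",
    "get_preset",
    "q_peak_from_re",
]

TEST_SECTION_DIAMETER_CM = 2.8

SALINE = FluidProperties(rho=1.0, mu=1.0)
BLOOD_ANALOGUE = FluidProperties(rho=1.0, mu=3.5)

# Leaflet constitutive sets (C10 kPa; k1, beta MPa as printed).  The
# pericardial mean fiber direction lies at 45 degrees in the leaflet plane.
MATERIALS = {
    "porcine": MaterialParams.from_printed(
        c10_kpa=0.302, c01=3.25, k1_mpa=0.197, k2=0.001, kappa=0.0,
        e0=(1.0, 0.0, 0.0)),
    "pericardial": MaterialParams.from_printed(
        c10_kpa=0.119, c01=22.59, k1_mpa=2.38, k2=149.8, kappa=0.292,
        e0=(np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0)),
}

FIBER_ANGLES = {"porcine": 0.0, "pericardial": np.pi / 4}


def q_peak_from_re(re_peak: float, d: float = TEST_SECTION_DIAMETER_CM,
                   fluid: FluidProperties = SALINE) -> float:
    """Peak flow (mL/s) implied by a peak Reynolds number in the test section:
    Q = Re * mu * A / (rho * D), A = pi D^2 / 4."""
    area = np.pi * d * d / 4.0
    return re_peak * cp_to_poise(fluid.mu) * area / (fluid.rho * d)


@dataclass(frozen=True)
class ExperimentPreset:
    """Targets and protocol flags for one synthetic pulse-duplicator run."""

    name: str  # "porcine" | "pericardial"
    heart_rate_bpm: float = 70.0
    sv_mean: float = 0.0  # mL, forward stroke volume of the mean flow
    sv_sd: float = 0.0  # mL, 10-cycle standard deviation
    dp_mean: float = 0.0  # mmHg, max forward-flow pressure difference
    dp_sd: float = 0.0  # mmHg
    re_peak: float = 0.0  # dimensionless, sets the target peak flow
    filter_cutoff_hz: float = 100.0
    filter_pressures: bool = True
    filter_flow: bool = True
    n_cycles: int = 10
    seed: int = 0
    fluid: FluidProperties = SALINE
    ejection_width_s: float = 0.24  # initial systolic ejection width
    flutter_freq_hz: float = 40.0
    flutter_amp_frac: float = 0.05
    sensor_noise_p_mmhg: float = 0.3
    sensor_noise_q_ml_s: float = 2.0

    def __post_init__(self):
        if self.sv_mean <= 0 or self.dp_mean <= 0 or self.re_peak <= 0:
            raise ValueError("preset targets must be positive")
        if self.sv_sd < 0 or self.dp_sd < 0:
            raise ValueError("target SDs must be non-negative")
        if self.q_peak <= self.sv_mean / self.period:
            raise ValueError("infeasible targets: peak flow below mean flow")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def q_peak(self) -> float:
        """Target peak aortic flow (mL/s), consistent with re_peak."""
        return q_peak_from_re(self.re_peak, fluid=self.fluid)

    @property
    def material(self) -> MaterialParams:
        return MATERIALS[self.name]


# The +- values are treated as 10-cycle standard deviations.  Pressure and
# flow channels of the porcine protocol are low-pass filtered at 100 Hz;
# pericardial pressure channels are recorded unfiltered.
PRESETS = {
    "porcine": ExperimentPreset(
        name="porcine", sv_mean=69.4, sv_sd=0.4, dp_mean=22.8, dp_sd=0.2,
        re_peak=20576.0, filter_pressures=True, filter_flow=True),
    "pericardial": ExperimentPreset(
        name="pericardial", sv_mean=71.6, sv_sd=0.7, dp_mean=19.7, dp_sd=0.5,
        re_peak=19330.0, filter_pressures=False, filter_flow=True),
}

# Published simulation-side summaries, used by the comparison reports.
COMPUTATIONAL_SUMMARIES = {
    "porcine": {"stroke_volume_mL": 72.7, "dp_max_mmHg": 22.4},
    "pericardial": {"stroke_volume_mL": 72.1, "dp_max_mmHg": 16.4},
}

WINDKESSELS = {
    "porcine": RCRWindkessel(r_c=0.0218, r_p=1.31, c=0.915),
    "pericardial": RCRWindkessel(r_c=0.0282, r_p=1.22, c=1.27),
}


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
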