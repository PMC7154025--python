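"""Unit conversion constants.

Internal mechanical units are kPa / cm / s; hemodynamic quantities are kept in
the clinical units the instruments report (mmHg, mL/s, cP) and converted at the
few points where the two systems meet (orifice Bernoulli law, membrane loading).
"""

MMHG_PER_DYN_CM2 = 1.0 / 1333.22
DYN_CM2_PER_MMHG = 1333.22
KPA_PER_MMHG = 0.133322
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG
KPA_PER_MPA = 1000.0
POISE_PER_CP = 0.01


def mpa_to_kpa(x: float) -> float:
    return x * KPA_PER_MPA


def kpa_to_mpa(x: float) -> float:
    return x / KPA_PER_MPA


def cp_to_poise(x: float) -> float:
    """Dynamic viscosity, centipoise -> g/(cm s)."""
    return x * POISE_PER_CP


def mmhg_to_kpa(x: float) -> float:
    return x * KPA_PER_MMHG


def mmhg_to_dyn_cm2(x: float) -> float:
    return x * DYN_CM2_PER_MMHG


def dyn_cm2_to_mmhg(x: float) -> float:
    return x * MMHG_PER_DYN_CM2
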