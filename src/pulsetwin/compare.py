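"""Twin-vs-experiment comparison reports.

Builds the table of relative L2 / Linf discrepancy norms for the three bulk
signals (P_LV, P_Ao, Q_Ao) over one cycle, plus the scalar hemodynamic
summaries (forward stroke volume, maximum forward-flow pressure difference,
peak Reynolds number).  The experimental cycles are ensemble-averaged first
and the simulation is aligned to the experimental mean at the beginning of
valve opening, mirroring the acquisition convention.
"""

from __future__ import annotations

import numpy as np

from .metrics import (ComparisonReport, align_on_onset, discrepancy,
                      max_forward_dp, re_peak, stroke_volume)
from .presets import TEST_SECTION_DIAMETER_CM

__all__ = ["compare_waveforms", "compare_twin_to_experiment"]

_SIGNALS = [("p_lv", "P_LV"), ("p_ao", "P_Ao"), ("q_ao", "Q_Ao")]


def compare_waveforms(sim: dict, exp: dict, fluid,
                      d: float = TEST_SECTION_DIAMETER_CM,
                      align: bool = True) -> ComparisonReport:
    """Compare one simulated cycle against one (mean) experimental cycle.

    ``sim`` and ``exp`` map signal keys p_lv / p_ao / q_ao to Waveforms on
    one-cycle grids.  Alignment shifts the experimental traces so the flow
    onset coincides with the simulated one.
    """
    report = ComparisonReport()
    exp_aligned = dict(exp)
    if align:
        shifted, shift = align_on_onset(sim["q_ao"], exp["q_ao"])
        report.alignment_shift_s = shift
        n = int(round(shift / exp["q_ao"].dt))
        for key in ("p_lv", "p_ao", "q_ao"):
            v = np.interp(sim[key].t, exp[key].t, exp[key].v)
            exp_aligned[key] = sim[key].with_values(
                np.roll(v, -n), name=exp[key].name, unit=exp[key].unit,
                provenance=exp[key].provenance)
    for key, label in _SIGNALS:
        report.l2[label] = 100.0 * discrepancy(sim[key], exp_aligned[key], 2)
        report.linf[label] = 100.0 * discrepancy(sim[key], exp_aligned[key],
                                                 np.inf)
    report.stroke_volume_sim = stroke_volume(sim["q_ao"])
    report.stroke_volume_exp = stroke_volume(exp_aligned["q_ao"])
    report.dp_max_sim = max_forward_dp(sim["p_lv"], sim["p_ao"], sim["q_ao"])
    report.dp_max_exp = max_forward_dp(exp_aligned["p_lv"],
                                       exp_aligned["p_ao"],
                                       exp_aligned["q_ao"])
    report.re_peak_sim = re_peak(float(np.max(sim["q_ao"].v)), d, fluid)
    report.re_peak_exp = re_peak(float(np.max(exp_aligned["q_ao"].v)), d, fluid)
    return report


def compare_twin_to_experiment(twin_result, dataset, fluid) -> ComparisonReport:
    """Compare a converged twin cycle against a synthetic experimental
    dataset (its ensemble-mean waveforms)."""
    sim = {k: twin_result.waveforms[k] for k, _ in _SIGNALS}
    exp = {k: dataset.mean_waveform(k) for k, _ in _SIGNALS}
    return compare_waveforms(sim, exp, fluid)
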