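"""Validation metrics for pulse-duplicator waveforms.

Implements the bulk-hemodynamic quantities used to compare a simulated cycle
against the (averaged) experimental one: relative L2/Linf discrepancy norms,
forward stroke volume, maximum forward-flow transvalvular pressure difference,
peak Reynolds number of the test section, and 10-cycle ensemble statistics
with 95% bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import cp_to_poise

__all__ = [
    "Waveform",
    "ComparisonReport",
    "discrepancy",
    "stroke_volume",
    "net_volume",
    "max_forward_dp",
    "re_peak",
    "ensemble_stats",
    "align_on_onset",
]


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled time series with a unit label.

    ``provenance`` distinguishes twin-simulated traces from the synthetic
    "experimental" ones produced by the generator.
    """

    t: np.ndarray  # s, uniform, strictly increasing
    v: np.ndarray
    unit: str = ""
    name: str = ""
    provenance: str = "simulated"
    cycle_index: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValueError("waveform needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform values must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def with_values(self, v, **kw) -> "Waveform":
        d = dict(t=self.t, v=np.asarray(v, dtype=float), unit=self.unit,
                 name=self.name, provenance=self.provenance,
                 cycle_index=self.cycle_index)
        d.update(kw)
        return Waveform(**d)


@dataclass
class ComparisonReport:
    """Per-signal discrepancy norms plus the scalar hemodynamic summaries."""

    l2: dict = field(default_factory=dict)  # signal -> relative L2, %
    linf: dict = field(default_factory=dict)  # signal -> relative Linf, %
    stroke_volume_sim: float = np.nan  # mL
    stroke_volume_exp: float = np.nan  # mL
    dp_max_sim: float = np.nan  # mmHg
    dp_max_exp: float = np.nan  # mmHg
    re_peak_sim: float = np.nan
    re_peak_exp: float = np.nan
    alignment_shift_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "discrepancy_l2_percent": dict(self.l2),
            "discrepancy_linf_percent": dict(self.linf),
            "stroke_volume_mL": {"simulation": self.stroke_volume_sim,
                                 "experiment": self.stroke_volume_exp},
            "dp_max_forward_mmHg": {"simulation": self.dp_max_sim,
                                    "experiment": self.dp_max_exp},
            "re_peak": {"simulation": self.re_peak_sim,
                        "experiment": self.re_peak_exp},
            "alignment_shift_s": self.alignment_shift_s,
        }


def _resample_to(m: Waveform, t: np.ndarray) -> np.ndarray:
    return np.interp(t, m.t, m.v)


def discrepancy(m_sim: Waveform, m_exp: Waveform, q) -> float:
    """Relative discrepancy ||sim - exp||_q / ||exp||_q over the reference span.

    q is 2 (L2 via trapezoidal quadrature) or inf (max absolute value); the
    simulation is linearly resampled onto the experimental grid.
    """
    t = m_exp.t
    if m_sim.t[0] > t[0] + m_exp.dt or m_sim.t[-1] < t[-1] - m_exp.dt:
        raise ValueError("waveform spans do not overlap the reference grid")
    sim = _resample_to(m_sim, t)
    diff = sim - m_exp.v
    if q == 2:
        num = np.sqrt(np.trapezoid(diff ** 2, t))
        den = np.sqrt(np.trapezoid(m_exp.v ** 2, t))
    elif q in (np.inf, "inf", float("inf")):
        num = np.max(np.abs(diff))
        den = np.max(np.abs(m_exp.v))
    else:
        raise ValueError("q must be 2 or inf")
    if den == 0:
        raise ZeroDivisionError("reference waveform has zero norm")
    return float(num / den)


def stroke_volume(q_ao: Waveform) -> float:
    """Forward stroke volume (mL): trapezoidal integral of the positive part
    of aortic flow over the cycle."""
    return float(np.trapezoid(np.maximum(q_ao.v, 0.0), q_ao.t))


def net_volume(q_ao: Waveform) -> float:
    """Net ejected volume (mL) including regurgitant flow."""
    return float(np.trapezoid(q_ao.v, q_ao.t))


def max_forward_dp(p_lv: Waveform, p_ao: Waveform, q_ao: Waveform) -> float:
    """Maximum transvalvular pressure difference (mmHg) over forward flow,
    max over {t : q_ao > 0} of (p_lv - p_ao)."""
    if not (len(p_lv.t) == len(p_ao.t) == len(q_ao.t)) or \
            not np.allclose(p_lv.t, q_ao.t) or not np.allclose(p_ao.t, q_ao.t):
        raise ValueError("signals must share a common time grid")
    mask = q_ao.v > 0.0
    if not np.any(mask):
        raise ValueError("no forward-flow samples in the cycle")
    return float(np.max(p_lv.v[mask] - p_ao.v[mask]))


def re_peak(q_peak: float, d: float, fluid) -> float:
    """Peak Reynolds number rho*Q_peak*D / (mu*A), A = pi D^2/4.

    q_peak in mL/s, d in cm, fluid.rho in g/cm^3, fluid.mu in cP.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    area = np.pi * d * d / 4.0
    mu = cp_to_poise(fluid.mu)
    return float(fluid.rho * q_peak * d / (mu * area))


def ensemble_stats(cycles: list[Waveform]):
    """Pointwise mean waveform and central 95% band over phase-aligned cycles.

    Returns (mean: Waveform, lo: ndarray, hi: ndarray) where lo/hi are the
    2.5 / 97.5 percentiles.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two cycles")
    t0 = cycles[0].t
    vals = np.empty((len(cycles), len(t0)))
    for i, c in enumerate(cycles):
        if len(c.t) != len(t0) or not np.allclose(c.t - c.t[0], t0 - t0[0]):
            raise ValueError("cycles must share a phase-aligned grid")
        vals[i] = c.v
    mean = cycles[0].with_values(vals.mean(axis=0), provenance="ensemble-mean")
    lo = np.percentile(vals, 2.5, axis=0)
    hi = np.percentile(vals, 97.5, axis=0)
    return mean, lo, hi


def align_on_onset(reference: Waveform, other: Waveform,
                   threshold_frac: float = 0.05) -> tuple[Waveform, float]:
    """Circularly shift ``other`` so its opening onset matches ``reference``.

    Onset is the first up-crossing of ``threshold_frac`` times the trace
    maximum; used to align experimental cycles with the simulation at the
    beginning of valve opening.  Returns the shifted waveform (on the
    reference grid) and the applied shift in seconds.
    """

    def onset_index(w: Waveform) -> int:
        thr = threshold_frac * np.max(w.v)
        above = w.v >= thr
        idx = np.argmax(above)
        return int(idx)

    i_ref = onset_index(reference)
    i_oth = onset_index(other)
    v = np.interp(reference.t, other.t - other.t[0] + reference.t[0], other.v,
                  period=other.t[-1] - other.t[0] + other.dt)
    shift = (i_oth - i_ref) * reference.dt
    n = int(round(shift / reference.dt))
    v = np.roll(v, -n)
    return reference.with_values(v, name=other.name, unit=other.unit,
                                 provenance=other.provenance), float(shift)
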