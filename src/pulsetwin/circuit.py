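"""Reduced-order pulse-duplicator circuit models.

The rig is represented as a lumped hydraulic network: a pump source drives a
ventricular node through the viscoelastic impedance adapter (VIA) elements,
the 0D valve surrogate connects the ventricular and aortic nodes, and a
three-element Windkessel (R-C-R) provides the downstream load.  Two upstream
topologies are supported, mirroring the two experimental configurations:

* porcine: pressure source P_pump -> R1 -> VIA node (C_VIA) -> R2 ->
  ventricular node (small regularizing compliance C_LV) -> valve -> aortic
  node -> Rc -> C -> Rp -> ground;
* pericardial: flow source Q_pump into node V1 (C_VIA1, drained by R_out to
  ground), V1 -> R_VIA -> ventricular node V2 (C_VIA2), atrial pressure
  source P_LA -> mitral diode (R_MV) -> V2, then valve and Windkessel as
  above.

All compliance values are interpreted as mL/mmHg (the physiological unit in
which the tabulated magnitudes are meaningful).  The ground/reservoir
pressure is 0 mmHg.

State vector: node pressures (mmHg), valve opening fraction theta, valve flow
q (mL/s; the orifice law carries an inertance, so flow is a dynamic state).
The closed-valve leak orifice makes the flow equation stiff during diastole,
so the default integrator is LSODA, which switches to a stiff method there;
any scipy ``solve_ivp`` method can be selected instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import signal
from scipy.integrate import solve_ivp

from .metrics import Waveform
from .valve import ValveParams, effective_area, pdva_proxy

__all__ = [
    "FluidProperties",
    "RCRWindkessel",
    "PorcineUpstream",
    "PericardialUpstream",
    "LinearValve",
    "CircuitConfig",
    "CircuitState",
    "PeriodicResult",
    "IntegrationFailure",
    "diode_flow",
    "rcr_outlet_update",
    "assemble_rhs",
    "run_to_periodic",
    "lowpass_filter",
]

_DYN = 1333.22  # dyn/cm^2 per mmHg
_A_EFF_MIN = 1e-10  # cm^2; below this the orifice is treated as sealed


class IntegrationFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Working fluid: saline by default, blood-analogue via mu = 3.5 cP."""

    rho: float = 1.0  # g/cm^3
    mu: float = 1.0  # cP

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class RCRWindkessel:
    r_c: float  # mmHg s/mL, characteristic resistance
    r_p: float  # mmHg s/mL, peripheral resistance
    c: float  # mL/mmHg, compliance

    def __post_init__(self):
        if min(self.r_c, self.r_p, self.c) <= 0:
            raise ValueError("Windkessel parameters must be positive")

    @property
    def tau(self) -> float:
        """Diastolic decay time constant r_p * c (s)."""
        return self.r_p * self.c


@dataclass(frozen=True)
class PorcineUpstream:
    """Pressure-source pump behind the VIA Windkessel (R1, C_VIA, R2)."""

    p_pump: Callable[[float], float]  # mmHg, periodic
    r1: float = 0.15  # mmHg s/mL
    r2: float = 0.15  # mmHg s/mL
    c_via: float = 0.1  # mL/mmHg

    def __post_init__(self):
        if min(self.r1, self.r2, self.c_via) <= 0:
            raise ValueError("upstream parameters must be positive")


@dataclass(frozen=True)
class PericardialUpstream:
    """Flow-source pump with two VIA compliances, return path and mitral diode."""

    q_pump: Callable[[float], float]  # mL/s, periodic
    p_la: Callable[[float], float]  # mmHg, periodic
    c_via1: float = 0.0275  # mL/mmHg
    c_via2: float = 0.0347  # mL/mmHg
    r_via: float = 0.15  # mmHg s/mL
    r_out: float = 0.0898  # mmHg s/mL, V1 -> ground return path
    r_mv: float = 0.0280  # mmHg s/mL, open mitral diode

    def __post_init__(self):
        if min(self.c_via1, self.c_via2, self.r_via, self.r_out, self.r_mv) <= 0:
            raise ValueError("upstream parameters must be positive")


@dataclass(frozen=True)
class LinearValve:
    """Fixed linear resistance standing in for the valve (verification aid)."""

    r: float  # mmHg s/mL
    inertance: float = 4.0e-4  # mmHg s^2/mL


@dataclass(frozen=True)
class CircuitConfig:
    fluid: FluidProperties
    upstream: PorcineUpstream | PericardialUpstream
    windkessel: RCRWindkessel
    valve: ValveParams | LinearValve
    c_lv: float = 0.02  # mL/mmHg, porcine ventricular-node regularization
    heart_rate_bpm: float = 70.0
    method: str = "LSODA"
    max_step: float = 1e-4  # s
    diode_eps: float = 0.01  # mmHg, mitral diode smoothing width

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def state_names(self) -> list[str]:
        up = ("p_via" if isinstance(self.upstream, PorcineUpstream) else "p_v1")
        return [up, "p_lv", "p_store", "theta", "q"]

    def with_valve(self, valve) -> "CircuitConfig":
        return replace(self, valve=valve)


@dataclass
class CircuitState:
    """Named view of one instant of the circuit state."""

    pressures: dict
    theta: float
    q: float
    time: float

    def __post_init__(self):
        vals = list(self.pressures.values()) + [self.theta, self.q, self.time]
        if not np.all(np.isfinite(vals)):
            raise ValueError("circuit state must be finite")
        if not -1e-9 <= self.theta <= 1.0 + 1e-9:
            raise ValueError("theta must lie in [0, 1]")


def diode_flow(p_up: float, p_down: float, r: float, eps_smooth: float = 0.01) -> float:
    """Smooth one-way (diode) flow law, ~ max(p_up - p_down, 0)/r with a C1
    regularization of width eps_smooth near zero pressure difference."""
    if r <= 0 or eps_smooth <= 0:
        raise ValueError("r and eps_smooth must be positive")
    dp = p_up - p_down
    return (dp + math.sqrt(dp * dp + eps_smooth * eps_smooth)) / (2.0 * r)


def rcr_outlet_update(wk: RCRWindkessel, q_in: float, p_store: float):
    """One evaluation of the three-element Windkessel: returns the inlet
    pressure seen by the upstream circuit and the stored-pressure rate,
    p_in = q_in r_c + p_store,  c dp_store/dt = q_in - p_store/r_p."""
    p_inlet = q_in * wk.r_c + p_store
    dp_store = (q_in - p_store / wk.r_p) / wk.c
    return p_inlet, dp_store


def _valve_terms(config: CircuitConfig, theta: float, q: float, dp: float):
    """(dtheta/dt, dq/dt) for the configured valve element."""
    v = config.valve
    if isinstance(v, LinearValve):
        return 0.0, (dp - v.r * q) / v.inertance
    theta_c = min(max(theta, 0.0), 1.0)
    a_eff = effective_area(theta_c, v)
    if a_eff < _A_EFF_MIN:
        # sealed orifice: relax any residual flow to zero
        dq = -q / 1e-3
    else:
        dp_bern = 0.5 * config.fluid.rho * q * abs(q) / (a_eff * a_eff) / _DYN
        dq = (dp - dp_bern) / v.inertance
    if dp >= 0.0:
        dtheta = v.k_open * (1.0 - theta_c) * dp
    else:
        dtheta = v.k_close * theta_c * dp
    return dtheta, dq


def assemble_rhs(config: CircuitConfig, y: np.ndarray, t: float) -> np.ndarray:
    """Time derivative of the circuit state vector at time t.

    State ordering follows :meth:`CircuitConfig.state_names`.  Flux balance
    holds at every compliance node; the aortic pressure is algebraic,
    p_ao = q r_c + p_store.
    """
    if not np.all(np.isfinite(y)):
        raise IntegrationFailure(f"non-finite state at t = {t:.6f} s: {y}")
    p_up_node, p_lv, p_store, theta, q = y
    wk = config.windkessel
    p_ao = q * wk.r_c + p_store
    dp_store = (q - p_store / wk.r_p) / wk.c
    dtheta, dq = _valve_terms(config, theta, q, p_lv - p_ao)

    up = config.upstream
    if isinstance(up, PorcineUpstream):
        q1 = (up.p_pump(t) - p_up_node) / up.r1
        q2 = (p_up_node - p_lv) / up.r2
        d_up = (q1 - q2) / up.c_via
        d_lv = (q2 - q) / config.c_lv
    else:
        q_via = (p_up_node - p_lv) / up.r_via
        d_up = (up.q_pump(t) - q_via - p_up_node / up.r_out) / up.c_via1
        q_mv = diode_flow(up.p_la(t), p_lv, up.r_mv, config.diode_eps)
        d_lv = (q_via + q_mv - q) / up.c_via2
    return np.array([d_up, d_lv, dp_store, dtheta, dq])


@dataclass
class PeriodicResult:
    waveforms: dict  # name -> Waveform over one period (1 kHz grid)
    states: np.ndarray  # (n_states, n_samples) sampled converged cycle
    state_names: list[str]
    n_cycles: int
    achieved_tol: float
    converged: bool
    y_final: np.ndarray = field(repr=False, default=None)


def _default_y0(config: CircuitConfig) -> np.ndarray:
    # aortic store pre-charged to a diastolic level to shorten the transient
    return np.array([10.0, 10.0, 80.0, 0.0, 0.0])


def run_to_periodic(config: CircuitConfig, dt: float = 1e-4,
                    max_cycles: int = 40, tol: float = 1e-3,
                    y0: np.ndarray | None = None) -> PeriodicResult:
    """Integrate the circuit cycle-by-cycle until the sampled state trajectory
    repeats to relative L2 tolerance ``tol``; returns the first converged
    cycle sampled uniformly at 1 kHz over one period (60/70 s at 70 bpm)."""
    T = config.period
    n_samp = int(round(T * 1000.0))
    t_eval = np.arange(n_samp) * 1e-3
    y = (_default_y0(config) if y0 is None else np.asarray(y0, dtype=float)).copy()

    def rhs(t, yv):
        return assemble_rhs(config, yv, t)

    prev = None
    achieved = np.inf
    n_done = 0
    samples = None
    for cycle in range(max_cycles):
        t0 = cycle * T
        sol = solve_ivp(rhs, (t0, t0 + T), y, method=config.method,
                        t_eval=t0 + t_eval, max_step=max(dt, config.max_step)
                        if config.method != "LSODA" else config.max_step,
                        rtol=1e-7, atol=1e-8, dense_output=False)
        if not sol.success:
            raise IntegrationFailure(
                f"integration failed in cycle {cycle}: {sol.message}")
        samples = sol.y
        y = sol.y[:, -1].copy()
        # continue to the exact period end (t_eval stops one sample short)
        tail = solve_ivp(rhs, (t0 + t_eval[-1], t0 + T), y, method=config.method,
                         max_step=config.max_step, rtol=1e-7, atol=1e-8)
        if not tail.success:
            raise IntegrationFailure(
                f"integration failed in cycle {cycle}: {tail.message}")
        y = tail.y[:, -1].copy()
        y[3] = min(max(y[3], 0.0), 1.0)
        n_done = cycle + 1
        if prev is not None:
            num = np.linalg.norm(samples - prev)
            den = np.linalg.norm(prev)
            achieved = num / den if den > 0 else num
            if achieved < tol:
                break
        prev = samples.copy()

    converged = achieved < tol
    names = config.state_names()
    wf = {}
    p_up, p_lv, p_store, theta, q = samples
    theta = np.clip(theta, 0.0, 1.0)
    p_ao = q * config.windkessel.r_c + p_store
    wf["p_lv"] = Waveform(t_eval, p_lv, unit="mmHg", name="P_LV")
    wf["p_ao"] = Waveform(t_eval, p_ao, unit="mmHg", name="P_Ao")
    wf["q_ao"] = Waveform(t_eval, q, unit="mL/s", name="Q_Ao")
    wf["theta"] = Waveform(t_eval, theta, unit="", name="theta")
    wf[names[0]] = Waveform(t_eval, p_up, unit="mmHg", name=names[0])
    wf["p_store"] = Waveform(t_eval, p_store, unit="mmHg", name="p_store")
    if isinstance(config.valve, ValveParams):
        wf["pdva"] = Waveform(t_eval, pdva_proxy(theta, config.valve),
                              unit="cm^2", name="PDVA")
    return PeriodicResult(waveforms=wf, states=samples, state_names=names,
                          n_cycles=n_done, achieved_tol=float(achieved),
                          converged=bool(converged), y_final=y)


def lowpass_filter(wave: Waveform, fc: float = 100.0) -> Waveform:
    """Zero-phase low-pass Butterworth filter (4th order, unit DC gain)."""
    if wave.fs <= 2.0 * fc:
        raise ValueError(
            f"sampling rate {wave.fs:.1f} Hz too coarse for fc = {fc} Hz")
    b, a = signal.butter(4, fc, fs=wave.fs)
    v = signal.filtfilt(b, a, wave.v)
    return wave.with_values(v)
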