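"""0D bioprosthetic-valve surrogate.

The full 3D fluid–structure interaction valve is replaced by a lumped model
with a single opening-fraction state theta in [0, 1]:

* a Mynard-type rate law, dtheta/dt = k_open (1-theta) dp for opening pressure
  differences and k_close theta dp for closing ones;
* a linear effective-orifice area A_eff = a_leak + (a_max - a_leak) theta;
* a Bernoulli orifice pressure–flow law with an inertance term,
  dp = rho/2 * q|q| / A_eff^2 + L dq/dt (converted dyn/cm^2 -> mmHg);
* an effective-orifice-area calibration that inverts the Bernoulli law against
  a known (peak flow, peak pressure difference) pair, in the spirit of the
  Gorlin equation;
* a quasi-static diastolic membrane state exercising the leaflet constitutive
  law: the closed valve is idealized as a pressurized spherical cap whose
  equibiaxial membrane tension balances the transvalvular load by Laplace's
  law, T(lambda) = dp * R / 2.

This surrogate is an explicit modeling substitution: the reference 3D model
has no 0D valve law (its resistance emerges from the FSI solve), and leaflet
flutter is intentionally not represented here (the synthetic-experiment
generator adds it to PDVA traces instead).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .constitutive import MaterialParams, plane_stress_biaxial
from .units import dyn_cm2_to_mmhg, mmhg_to_kpa

__all__ = [
    "ValveParams",
    "ValveState",
    "valve_rate",
    "effective_area",
    "valve_pressure_flow",
    "solve_orifice_flow",
    "calibrate_eoa",
    "diastolic_membrane_state",
    "pdva_proxy",
]


@dataclass(frozen=True)
class ValveParams:
    a_max: float  # cm^2, maximal effective orifice area
    material: MaterialParams
    a_leak: float | None = None  # cm^2; default 0.001 * a_max
    k_open: float = 3.0  # 1/(mmHg s)
    k_close: float = 3.0  # 1/(mmHg s)
    inertance: float = 4.0e-4  # mmHg s^2/mL
    cap_radius: float = 1.25  # cm
    thickness: float = 0.04  # cm
    pdva_scale: float | None = None  # cm^2; default a_max / 0.7

    def __post_init__(self):
        if self.a_leak is None:
            object.__setattr__(self, "a_leak", 1e-3 * self.a_max)
        if not self.a_max > self.a_leak >= 0:
            raise ValueError("need a_max > a_leak >= 0")
        if self.k_open <= 0 or self.k_close <= 0:
            raise ValueError("rate coefficients must be positive")
        if self.pdva_scale is None:
            # discharge-coefficient convention: projected area > effective area
            object.__setattr__(self, "pdva_scale", self.a_max / 0.7)

    def with_eoa(self, a_max: float) -> "ValveParams":
        return replace(self, a_max=a_max, a_leak=None, pdva_scale=None)


@dataclass(frozen=True)
class ValveState:
    theta: float
    q: float  # mL/s

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def valve_rate(theta: float, dp: float, params: ValveParams) -> float:
    """Opening-fraction rate dtheta/dt for transvalvular pressure dp (mmHg).

    Positive dp opens at k_open*(1-theta)*dp, negative dp closes at
    k_close*theta*dp; the (1-theta)/theta factors saturate the state inside
    [0, 1] smoothly.
    """
    theta = min(max(theta, 0.0), 1.0)
    if dp >= 0.0:
        return params.k_open * (1.0 - theta) * dp
    return params.k_close * theta * dp


def effective_area(theta: float, params: ValveParams) -> float:
    """Effective orifice area (cm^2), linear in the opening fraction."""
    theta = min(max(theta, 0.0), 1.0)
    return params.a_leak + (params.a_max - params.a_leak) * theta


def valve_pressure_flow(q: float, dq_dt: float, theta: float, fluid,
                        params: ValveParams) -> float:
    """Transvalvular pressure difference (mmHg) for flow q (mL/s) through the
    orifice: Bernoulli quadratic loss plus inertance."""
    a_eff = effective_area(theta, params)
    if a_eff <= 0:
        raise ValueError("effective area must be positive")
    dp_dyn = 0.5 * fluid.rho * q * abs(q) / (a_eff * a_eff)
    return dyn_cm2_to_mmhg(dp_dyn) + params.inertance * dq_dt


def solve_orifice_flow(dp: float, theta: float, fluid, params: ValveParams,
                       r_series: float = 0.0) -> float:
    """Quasi-steady flow (mL/s) through the orifice for a driving pressure dp
    (mmHg), optionally in series with a linear resistance.  Inverts
    a q|q| + r q = dp in closed form."""
    a_eff = effective_area(theta, params)
    a = dyn_cm2_to_mmhg(0.5 * fluid.rho / (a_eff * a_eff))
    s = 1.0 if dp >= 0 else -1.0
    mag = abs(dp)
    if a == 0:
        return s * mag / r_series
    return s * (-r_series + np.sqrt(r_series * r_series + 4.0 * a * mag)) / (2.0 * a)


def calibrate_eoa(q_peak: float, dp_peak: float, fluid) -> float:
    """Effective orifice area (cm^2) from a (peak flow, peak forward pressure
    difference) pair by inverting the Bernoulli law:
    EOA = Q_peak * sqrt(rho / (2 dp_peak))."""
    if dp_peak <= 0:
        raise ValueError("dp_peak must be positive")
    dp_dyn = dp_peak * 1333.22
    return float(q_peak * np.sqrt(fluid.rho / (2.0 * dp_dyn)))


def diastolic_membrane_state(params: ValveParams, dp: float,
                             lam_max: float = 2.0):
    """Quasi-static loaded state of the closed leaflet under diastolic
    pressure dp (mmHg).

    Solves the Laplace balance T(lambda) = dp * cap_radius / 2 for the
    equibiaxial stretch of a spherical-cap membrane, where the tension
    T = thickness * mean in-plane Cauchy stress comes from the constitutive
    law.  Returns (lambda, tension kPa*cm, peak von Mises stress kPa).
    """
    if dp < 0:
        raise ValueError("diastolic load must be non-negative")
    if dp == 0.0:
        return 1.0, 0.0, 0.0
    target = mmhg_to_kpa(dp) * params.cap_radius / 2.0  # kPa*cm

    def tension(lam: float) -> float:
        s11, s22, _ = plane_stress_biaxial(params.material, lam, lam)
        return params.thickness * 0.5 * (s11 + s22)

    f = lambda lam: tension(lam) - target
    lo, hi = 1.0 + 1e-12, 1.05
    while f(hi) < 0.0:
        hi *= 1.05
        if hi > lam_max:
            raise RuntimeError(
                f"no membrane equilibrium bracket in stretch range (1, {lam_max}]")
    lam = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    s11, s22, _ = plane_stress_biaxial(params.material, lam, lam)
    t = params.thickness * 0.5 * (s11 + s22)
    # von Mises of the plane-stress state (sigma33 = 0)
    vm = float(np.sqrt(s11 * s11 - s11 * s22 + s22 * s22))
    return float(lam), float(t), vm


def pdva_proxy(theta_trace, params: ValveParams):
    """Projected dynamic valve area trace (cm^2) from an opening-fraction
    trace: PDVA(t) = pdva_scale * theta(t), on the same grid."""
    return params.pdva_scale * np.asarray(theta_trace, dtype=float)
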