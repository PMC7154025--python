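"""Leaflet and wall solid mechanics.

The leaflets are modeled as incompressible, anisotropic, hyperelastic membranes
using a Holzapfel–Gasser–Ogden-type strain energy with collagen fiber angle
dispersion.  The strain energy splits into isochoric and volumetric parts,

    Psi(F) = W(Fbar) + U(J),    Fbar = J^(-1/3) F,   J = det F,

with an exponential neo-Hookean matrix term

    W_iso = C10 * (exp(C01 * (I1bar - 3)) - 1),

a dispersed fiber reinforcement term

    W_aniso = k1/(2 k2) * (exp(k2 * E^2) - 1),
    E = kappa * I1bar + (1 - 3 kappa) * I4bar* - 1,

where I4bar* = max(e0' Cbar e0, 1) switches the fibers off in compression and
kappa in [0, 1/3] interpolates between perfectly aligned (0) and isotropic
(1/3) fiber distributions, and a volumetric stabilization

    U(J) = beta * (J ln J - J + 1).

The first Piola–Kirchhoff stress is the analytic gradient P = dPsi/dF; a
finite-difference cross-check lives in the test suite.  The fiber exponential
is evaluated through expm1 so the nearly-quadratic small-k2 regime (porcine
k2 = 0.001) does not suffer cancellation; the k2 -> 0 limit is (k1/2) E^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .units import mpa_to_kpa

__all__ = [
    "MaterialParams",
    "DeformationState",
    "StressResult",
    "WallParams",
    "FitResult",
    "NonIdentifiableWarning",
    "InvalidDeformationError",
    "EnergyOverflowError",
    "compute_invariants",
    "strain_energy",
    "strain_energy_of_F",
    "pk1_stress",
    "plane_stress_biaxial",
    "fit_material_params",
    "wall_strain_energy",
    "wall_tether_force",
]

# exponent guard for the fiber term: exp(700) is near the float64 ceiling
_EXP_ARG_MAX = 250.0


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive determinant."""


class EnergyOverflowError(OverflowError):
    """Fiber exponential overflow; names the offending invariant."""


class NonIdentifiableWarning(UserWarning):
    """Fit requested with parameters the data cannot constrain."""


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants for one leaflet material.

    Stress-like constants are stored in kPa; use :meth:`from_printed` to enter
    k1 and beta_vol in MPa as they are usually tabulated.
    """

    c10: float  # kPa
    c01: float  # dimensionless
    k1: float  # kPa
    k2: float  # dimensionless
    kappa: float  # dimensionless, in [0, 1/3]
    e0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    beta_vol: float = mpa_to_kpa(14.1)  # kPa

    def __post_init__(self):
        if self.c10 <= 0 or self.c01 <= 0:
            raise ValueError("c10 and c01 must be positive")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError("kappa must lie in [0, 1/3]")
        e0 = np.asarray(self.e0, dtype=float)
        n = np.linalg.norm(e0)
        if n == 0:
            raise ValueError("e0 must be a nonzero vector")
        object.__setattr__(self, "e0", e0 / n)

    @classmethod
    def from_printed(cls, c10_kpa, c01, k1_mpa, k2, kappa, e0=(1.0, 0.0, 0.0),
                     beta_mpa=14.1) -> "MaterialParams":
        """Build from constants as printed: C10 in kPa, k1 and beta in MPa."""
        return cls(c10=c10_kpa, c01=c01, k1=mpa_to_kpa(k1_mpa), k2=k2,
                   kappa=kappa, e0=np.asarray(e0, dtype=float),
                   beta_vol=mpa_to_kpa(beta_mpa))

    def with_fiber(self, e0) -> "MaterialParams":
        return replace(self, e0=np.asarray(e0, dtype=float))


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities derived from a deformation gradient."""

    F: np.ndarray
    J: float
    Fbar: np.ndarray
    Cbar: np.ndarray
    i1bar: float
    i4bar: float
    i4bar_star: float


@dataclass(frozen=True)
class StressResult:
    pk1: np.ndarray  # kPa
    cauchy: np.ndarray  # kPa
    von_mises: float  # kPa


@dataclass(frozen=True)
class WallParams:
    """Penalty model of the (effectively rigid) glass test section."""

    c_wall: float = 33.1  # kPa
    kappa_wall: float = mpa_to_kpa(852.0)  # kPa / cm^2

    def __post_init__(self):
        if self.c_wall <= 0 or self.kappa_wall <= 0:
            raise ValueError("wall parameters must be positive")


def compute_invariants(F: np.ndarray, e0: np.ndarray) -> DeformationState:
    """Isochoric invariants of a deformation gradient.

    Returns J, I1bar = tr(Cbar) and the clamped fourth invariant
    I4bar* = max(e0' Cbar e0, 1), which is active in fiber extension only.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be a 3x3 tensor")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det(F) = {J:.6g} is not positive")
    e0 = np.asarray(e0, dtype=float)
    e0 = e0 / np.linalg.norm(e0)
    Fbar = J ** (-1.0 / 3.0) * F
    Cbar = Fbar.T @ Fbar
    i1bar = float(np.trace(Cbar))
    i4bar = float(e0 @ Cbar @ e0)
    return DeformationState(F=F, J=J, Fbar=Fbar, Cbar=Cbar, i1bar=i1bar,
                            i4bar=i4bar, i4bar_star=max(i4bar, 1.0))


def _fiber_pseudo_invariant(params: MaterialParams, state: DeformationState) -> float:
    return (params.kappa * state.i1bar
            + (1.0 - 3.0 * params.kappa) * state.i4bar_star - 1.0)


def _w_aniso(k1: float, k2: float, e: float) -> float:
    arg = k2 * e * e
    if arg > _EXP_ARG_MAX:
        raise EnergyOverflowError(
            "fiber energy exponent k2*E^2 = "
            f"{arg:.3g} overflows (E = kappa*I1bar + (1-3kappa)*I4bar* - 1 = {e:.4g})")
    if k2 == 0.0:
        return 0.5 * k1 * e * e
    return k1 / (2.0 * k2) * np.expm1(arg)


def strain_energy(params: MaterialParams, state: DeformationState) -> float:
    """Strain-energy density (kPa) for a given deformation state."""
    w_iso = params.c10 * np.expm1(params.c01 * (state.i1bar - 3.0))
    e = _fiber_pseudo_invariant(params, state)
    w_aniso = _w_aniso(params.k1, params.k2, e)
    J = state.J
    u = params.beta_vol * (J * np.log(J) - J + 1.0)
    return float(w_iso + w_aniso + u)


def strain_energy_of_F(params: MaterialParams, F: np.ndarray) -> float:
    return strain_energy(params, compute_invariants(F, params.e0))


def pk1_stress(params: MaterialParams, F: np.ndarray) -> StressResult:
    """Analytic first Piola–Kirchhoff, Cauchy, and von Mises stress (kPa)."""
    state = compute_invariants(F, params.e0)
    F = state.F
    J = state.J
    Finv_T = np.linalg.inv(F).T
    J23 = J ** (-2.0 / 3.0)

    # d(I1bar)/dF and d(I4bar)/dF; the clamp makes the fiber term one-sided
    dI1 = 2.0 * J23 * F - (2.0 / 3.0) * state.i1bar * Finv_T
    fe = F @ params.e0
    dI4 = 2.0 * J23 * np.outer(fe, params.e0) - (2.0 / 3.0) * state.i4bar * Finv_T

    dW_dI1 = params.c10 * params.c01 * np.exp(params.c01 * (state.i1bar - 3.0))
    e = _fiber_pseudo_invariant(params, state)
    arg = params.k2 * e * e
    if arg > _EXP_ARG_MAX:
        raise EnergyOverflowError(
            "fiber energy exponent k2*E^2 = "
            f"{arg:.3g} overflows (E = kappa*I1bar + (1-3kappa)*I4bar* - 1 = {e:.4g})")
    dW_dE = params.k1 * e * np.exp(arg)
    fiber_active = 1.0 if state.i4bar > 1.0 else 0.0

    P = (dW_dI1 + params.kappa * dW_dE) * dI1 \
        + (1.0 - 3.0 * params.kappa) * dW_dE * fiber_active * dI4 \
        + params.beta_vol * J * np.log(J) * Finv_T

    cauchy = (P @ F.T) / J
    cauchy = 0.5 * (cauchy + cauchy.T)  # symmetrize rounding noise
    dev = cauchy - np.trace(cauchy) / 3.0 * np.eye(3)
    vm = float(np.sqrt(1.5 * np.sum(dev * dev)))
    return StressResult(pk1=P, cauchy=cauchy, von_mises=vm)


def plane_stress_biaxial(params: MaterialParams, lam1: float, lam2: float,
                         fiber_angle: float = 0.0):
    """In-plane Cauchy stresses of an incompressible biaxial membrane state.

    F = diag(lam1, lam2, 1/(lam1*lam2)); the mean fiber direction lies in the
    membrane plane at ``fiber_angle`` from axis 1.  The hydrostatic pressure is
    eliminated by the traction-free thickness direction (sigma_33 = 0).
    Returns (sigma11, sigma22, sigma12) in kPa.
    """
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("stretches must be positive")
    F = np.diag([lam1, lam2, 1.0 / (lam1 * lam2)])
    p = params.with_fiber([np.cos(fiber_angle), np.sin(fiber_angle), 0.0])
    sig = pk1_stress(p, F).cauchy
    sig = sig - sig[2, 2] * np.eye(3)
    return float(sig[0, 0]), float(sig[1, 1]), float(sig[0, 1])


# ---------------------------------------------------------------------------
# Biaxial parameter fitting


@dataclass
class FitResult:
    params: MaterialParams
    residual: float  # root-mean-square stress residual, kPa
    r_squared: float
    n_points: int
    converged: bool
    message: str = ""


_FIT_BOUNDS = {
    # (lower, upper); k1 bounds in kPa
    "c10": (1e-4, 50.0),
    "c01": (0.1, 60.0),
    "k1": (0.0, 1e4),
    "k2": (0.0, 500.0),
    "kappa": (0.0, 1.0 / 3.0),
}


def _predict_stresses(theta, kappa_fixed, fiber_angle, lam1, lam2, beta_vol):
    c10, c01, k1, k2 = theta[:4]
    kappa = theta[4] if kappa_fixed is None else kappa_fixed
    p = MaterialParams(c10=c10, c01=c01, k1=k1, k2=k2, kappa=kappa,
                       beta_vol=beta_vol)
    out = np.empty((len(lam1), 2))
    for i, (l1, l2) in enumerate(zip(lam1, lam2)):
        s11, s22, _ = plane_stress_biaxial(p, l1, l2, fiber_angle)
        out[i] = (s11, s22)
    return out


def fit_material_params(data, init: MaterialParams, bounds: dict | None = None,
                        fixed_kappa: float | None = None,
                        fiber_angle: float = 0.0,
                        n_starts: int = 4, seed: int = 0) -> FitResult:
    """Fit constitutive constants to biaxial stress–stretch data.

    ``data`` is a DataFrame-like with columns ``protocol_id, lam1, lam2,
    sigma11_kPa, sigma22_kPa``.  Unweighted nonlinear least squares on the
    stacked in-plane Cauchy stresses, multi-started from bounds-scaled
    perturbations of ``init``.  When ``fixed_kappa`` is given the dispersion
    parameter is held; otherwise the data must contain at least two distinct
    loading protocols, or a :class:`NonIdentifiableWarning` is issued.
    """
    lam1 = np.asarray(data["lam1"], dtype=float)
    lam2 = np.asarray(data["lam2"], dtype=float)
    sig = np.column_stack([np.asarray(data["sigma11_kPa"], dtype=float),
                           np.asarray(data["sigma22_kPa"], dtype=float)])
    protocols = np.asarray(data["protocol_id"])
    if fixed_kappa is None and len(np.unique(protocols)) < 2:
        warnings.warn(
            "single-protocol biaxial data cannot identify the dispersion "
            "parameter kappa; fix kappa or add protocols",
            NonIdentifiableWarning, stacklevel=2)

    bounds = {**_FIT_BOUNDS, **(bounds or {})}
    names = ["c10", "c01", "k1", "k2"] + ([] if fixed_kappa is not None else ["kappa"])
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    x0 = np.array([init.c10, init.c01, init.k1, init.k2]
                  + ([] if fixed_kappa is not None else [init.kappa]))
    x0 = np.clip(x0, lo, hi)

    def resid(theta):
        try:
            pred = _predict_stresses(theta, fixed_kappa, fiber_angle, lam1,
                                     lam2, init.beta_vol)
        except (EnergyOverflowError, FloatingPointError):
            return np.full(sig.size, 1e6)
        r = (pred - sig).ravel()
        return np.where(np.isfinite(r), r, 1e6)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        if start == 0:
            x_start = x0
        else:
            # bounds-scaled jitter around the initial guess
            span = hi - lo
            x_start = np.clip(x0 * rng.uniform(0.5, 2.0, size=x0.shape)
                              + 0.05 * span * rng.standard_normal(x0.shape),
                              lo, hi)
        try:
            sol = optimize.least_squares(resid, x_start, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    theta = best.x
    kappa = fixed_kappa if fixed_kappa is not None else theta[4]
    fitted = MaterialParams(c10=theta[0], c01=theta[1], k1=theta[2],
                            k2=theta[3], kappa=min(kappa, 1.0 / 3.0),
                            e0=init.e0, beta_vol=init.beta_vol)
    r = resid(theta)
    ss_res = float(np.sum(r ** 2))
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    converged = bool(best.status > 0)
    msg = best.message if converged else (
        f"fit did not converge; best RMS residual {np.sqrt(ss_res / r.size):.4g} kPa")
    return FitResult(params=fitted, residual=float(np.sqrt(ss_res / r.size)),
                     r_squared=r2, n_points=len(lam1), converged=converged,
                     message=msg)


# ---------------------------------------------------------------------------
# Test-section wall model


def wall_strain_energy(wall: WallParams, F: np.ndarray) -> float:
    """Neo-Hookean penalty energy of the test-section wall (kPa)."""
    state = compute_invariants(F, np.array([1.0, 0.0, 0.0]))
    return 0.5 * wall.c_wall * (state.i1bar - 3.0)


def wall_tether_force(wall: WallParams, X: np.ndarray, chi: np.ndarray) -> np.ndarray:
    """Tether force density kappa_wall * (X - chi) pulling a material point
    back toward its reference position (kPa/cm per unit volume)."""
    return wall.kappa_wall * (np.asarray(X, dtype=float) - np.asarray(chi, dtype=float))
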