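"""Series solutions of diffusion into a sphere with a held surface concentration.

For a sphere of radius R initially empty (n = 0) whose surface is held at
n0, the classical separation-of-variables solution is

    n(t, r)/n0 = 1 + (2 R / (pi r)) * sum_{k>=1} ((-1)^k / k)
                     * sin(k pi r / R) * exp(-D_eff k^2 pi^2 t / R^2)

with the r -> 0 limit 1 + 2 sum_k (-1)^k exp(-D_eff k^2 pi^2 t / R^2), and
the fractional uptake

    M(t)/M_inf = 1 - (6 / pi^2) * sum_{k>=1} k^-2 exp(-D_eff k^2 pi^2 t / R^2).

The magnetic field enters only through D_eff = D (1 - beta): solutions
depend on (D, beta, t) solely through the product D (1 - beta) t, which is
the self-similarity the tests exploit.  Also provided: the 1D point-source
Gaussian kernel whose spread defines the characteristic time tau_0 = L^2/D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .physics import DiffusionSuppressedError, InvalidParameterError

__all__ = [
    "SphereProblem",
    "SeriesControl",
    "ConcentrationField",
    "UptakeCurve",
    "SeriesAccuracyWarning",
    "sphere_concentration",
    "sphere_uptake",
    "uptake_curve_for_beta",
    "concentration_grid",
    "point_source_1d",
]


class SeriesAccuracyWarning(UserWarning):
    """Truncated series may not have converged to the requested tail tolerance."""


@dataclass(frozen=True)
class SphereProblem:
    """Diffusion in a sphere: geometry, effective diffusivity, boundary data.

    ``initial_profile`` is g(r) on [0, R]; the analytic path supports only
    g = 0 (leave as None), arbitrary bounded g goes through the numeric
    solver.
    """

    R_sphere: float
    D_eff: float
    n0: float = 1.0
    initial_profile: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.R_sphere > 0:
            raise InvalidParameterError("sphere radius must be > 0")
        if not self.D_eff > 0:
            raise DiffusionSuppressedError(
                "effective diffusivity must be > 0 (beta >= 1 rejected upstream)"
            )
        if not self.n0 > 0:
            raise InvalidParameterError("surface concentration n0 must be > 0")


@dataclass(frozen=True)
class SeriesControl:
    """Truncation control for the infinite sums."""

    max_terms: int = 200
    tail_tolerance: float = 1e-10
    #: dimensionless-time floor D_eff*t/R^2 below which convergence within
    #: max_terms is not guaranteed and a warning is attached
    min_dimensionless_time: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_terms < 1:
            raise InvalidParameterError("max_terms must be >= 1")
        if not self.tail_tolerance > 0:
            raise InvalidParameterError("tail_tolerance must be > 0")


@dataclass(frozen=True)
class ConcentrationField:
    """(times x radii) grid of n(t, r)/n0 values."""

    times: np.ndarray
    radii: np.ndarray
    values: np.ndarray
    provenance: str  # "analytic" | "numeric"

    _BOUND_TOL = 1e-6  # Gibbs tolerance for exported grids near t = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(t) <= 0) or np.any(np.diff(r) <= 0):
            raise InvalidParameterError("times and radii must be strictly ascending")
        if v.shape != (t.size, r.size):
            raise InvalidParameterError("values must be shaped (n_times, n_radii)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class UptakeCurve:
    """Fractional uptake M(t)/M_inf sampled at the given times."""

    times: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "fraction", np.asarray(self.fraction, dtype=float))


DEFAULT_CONTROL = SeriesControl()


def _num_terms(tau: float, control: SeriesControl) -> int:
    """Terms needed so the first dropped exponential is below tail_tolerance."""
    if tau <= 0:
        return control.max_terms
    k = math.sqrt(max(-math.log(control.tail_tolerance), 0.0) / (math.pi**2 * tau))
    k = min(math.ceil(k), control.max_terms)
    return max(k, 1)


def _warn_if_underresolved(tau: float, control: SeriesControl) -> None:
    if 0 < tau < control.min_dimensionless_time:
        warnings.warn(
            f"dimensionless time D_eff*t/R^2 = {tau:.3g} is below "
            f"{control.min_dimensionless_time:g}; series truncated at "
            f"{control.max_terms} terms may show Gibbs oscillations",
            SeriesAccuracyWarning,
            stacklevel=3,
        )


def sphere_concentration(
    problem: SphereProblem,
    t: float,
    r: float,
    control: SeriesControl = DEFAULT_CONTROL,
) -> float:
    """Normalized concentration n(t, r)/n0 for the initially empty sphere.

    The series is truncated once the exponential tail falls below
    ``control.tail_tolerance``; at r = 0 the analytic center limit is used
    instead of dividing by r.
    """
    if problem.initial_profile is not None:
        raise InvalidParameterError(
            "analytic solution requires zero initial profile; "
            "use the numeric solver for general g(r)"
        )
    R = problem.R_sphere
    if t < 0:
        raise InvalidParameterError("time must be >= 0")
    if r < 0 or r > R:
        raise InvalidParameterError("radius must lie in [0, R]")
    tau = problem.D_eff * t / R**2
    if t == 0:
        return 1.0 if r == R else 0.0
    if r == R:
        return 1.0
    _warn_if_underresolved(tau, control)
    K = _num_terms(tau, control)
    k = np.arange(1, K + 1)
    decay = np.exp(-(k**2) * math.pi**2 * tau)
    sign = np.where(k % 2 == 0, 1.0, -1.0)
    if r == 0.0:
        return float(1.0 + 2.0 * np.sum(sign * decay))
    series = np.sum(sign / k * np.sin(k * math.pi * r / R) * decay)
    return float(1.0 + (2.0 * R / (math.pi * r)) * series)


def sphere_uptake(
    problem: SphereProblem,
    t: float,
    control: SeriesControl = DEFAULT_CONTROL,
) -> float:
    """Fractional uptake M(t)/M_inf of the initially empty sphere."""
    if t < 0:
        raise InvalidParameterError("time must be >= 0")
    if t == 0:
        return 0.0
    tau = problem.D_eff * t / problem.R_sphere**2
    _warn_if_underresolved(tau, control)
    K = _num_terms(tau, control)
    k = np.arange(1, K + 1)
    series = np.sum(np.exp(-(k**2) * math.pi**2 * tau) / k**2)
    return float(1.0 - (6.0 / math.pi**2) * series)


def uptake_curve_for_beta(
    D: float,
    beta_value: float,
    R_sphere: float,
    times: Sequence[float],
    control: SeriesControl = DEFAULT_CONTROL,
) -> UptakeCurve:
    """Uptake curve with the magnetic field folded in via D_eff = D (1 - beta).

    ``beta_value`` > 0 (paramagnet) lowers the whole curve, < 0 (diamagnet)
    raises it; beta >= 1 has no well-posed forward dynamics and raises.
    """
    if beta_value >= 1.0:
        raise DiffusionSuppressedError("beta >= 1: diffusion suppressed")
    problem = SphereProblem(R_sphere=R_sphere, D_eff=D * (1.0 - beta_value))
    t = np.asarray(times, dtype=float)
    frac = np.array([sphere_uptake(problem, float(ti), control) for ti in t])
    return UptakeCurve(times=t, fraction=frac)


def concentration_grid(
    problem: SphereProblem,
    times: Sequence[float],
    radii: Sequence[float],
    control: SeriesControl = DEFAULT_CONTROL,
    clamp: bool = True,
) -> ConcentrationField:
    """Evaluate the series on a (times x radii) grid for export/plotting.

    Exported grids are clamped to [0, 1] to suppress Gibbs over/undershoot
    near t = 0 (raw point evaluations via :func:`sphere_concentration` are
    never clamped).
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(radii, dtype=float)
    values = np.empty((t.size, r.size))
    for i, ti in enumerate(t):
        for j, rj in enumerate(r):
            values[i, j] = sphere_concentration(problem, float(ti), float(rj), control)
    if clamp:
        values = np.clip(values, 0.0, 1.0)
    return ConcentrationField(times=t, radii=r, values=values, provenance="analytic")


def point_source_1d(x: float | np.ndarray, t: float, D: float) -> float | np.ndarray:
    """Unit-mass 1D Gaussian kernel n(x, t) = (4 pi D t)^(-1/2) exp(-x^2 / 4 D t).

    The fundamental solution of 1D diffusion: integrates to 1 over x for
    every t > 0 and has second moment 2 D t, so the spread reaches a length
    L after tau_0 ~ L^2/D — the origin of the characteristic-time estimate.
    """
    if not t > 0:
        raise InvalidParameterError("time must be > 0 for the point-source kernel")
    if not D > 0:
        raise InvalidParameterError("diffusion coefficient D must be > 0")
    x = np.asarray(x, dtype=float)
    out = np.exp(-(x**2) / (4.0 * D * t)) / math.sqrt(4.0 * math.pi * D * t)
    return float(out) if out.ndim == 0 else out
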