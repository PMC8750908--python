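"""Closed-form magneto-diffusion quantities.

In a uniform static magnetic field, a magnetizable solute with a spatial
concentration gradient experiences a body force f = chi * B^2 * grad(n) / (2 mu0)
(parallel to the gradient for paramagnets, antiparallel for diamagnets).
Folding the resulting drift into Fick's law via the Nernst-Einstein mobility
yields an effective diffusion coefficient

    D_eff = D * (1 - beta),    beta = chi * B^2 / (2 mu0 R T),

so a field slows paramagnetic diffusion (beta > 0), accelerates diamagnetic
diffusion (beta < 0), and stops paramagnetic diffusion entirely at the
critical field where beta = 1.  Everything here is SI throughout: chi is the
*molar* magnetic susceptibility in m^3/mol, signed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "FieldCondition",
    "BetaResult",
    "CONSTANTS",
    "InvalidParameterError",
    "UndefinedOnsetError",
    "NoCriticalFieldError",
    "DiffusionSuppressedError",
    "beta",
    "effective_diffusion",
    "onset_field",
    "critical_field",
    "force_density",
    "force_per_molecule",
    "drift_velocity",
    "magnetic_pressure",
    "characteristic_time",
    "gradient_force_ratio",
    "ONSET_BETA",
]

#: Conventional onset threshold: |beta| = 0.05 changes the characteristic
#: diffusion time by ~5%, taken as the start of a detectable field effect.
ONSET_BETA = 0.05


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class UndefinedOnsetError(InvalidParameterError):
    """Onset field is undefined (chi = 0: the species is non-magnetic)."""


class NoCriticalFieldError(InvalidParameterError):
    """Critical field requested for a non-paramagnetic species (chi <= 0)."""


class DiffusionSuppressedError(InvalidParameterError):
    """beta >= 1: effective diffusivity is non-positive, dynamics ill-posed."""


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants used by every calculator.

    ``R_gas`` defaults to 8.31 J/(K mol) — the two-decimal value the onset
    table is tabulated with — rather than the CODATA 8.31446; override if
    full precision is wanted.  ``R_gas / N_A`` must agree with ``k_B`` to
    0.1% so the molar (R T) and molecular (k_B T) mobility routes are
    mutually consistent.
    """

    mu0: float = 4.0e-7 * math.pi  # vacuum permeability, T m / A
    R_gas: float = 8.31            # molar gas constant, J / (K mol)
    k_B: float = 1.380649e-23      # Boltzmann constant, J / K
    N_A: float = 6.02214076e23     # Avogadro constant, 1 / mol

    def __post_init__(self) -> None:
        for name in ("mu0", "R_gas", "k_B", "N_A"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if abs(self.R_gas / (self.N_A * self.k_B) - 1.0) > 1e-3:
            raise InvalidParameterError(
                "inconsistent constants: R_gas / N_A must equal k_B to 0.1%"
            )


#: Default constants instance shared by all operations.
CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class FieldCondition:
    """A (B, T) pair: magnetic induction in tesla, temperature in kelvin."""

    B: float
    T: float = 300.0

    def __post_init__(self) -> None:
        if not self.B >= 0:
            raise InvalidParameterError("magnetic induction B must be >= 0")
        if not self.T > 0:
            raise InvalidParameterError("temperature T must be > 0")


# Regime vocabulary for BetaResult.
REGIME_DIAMAGNETIC = "diamagnetic-accelerated"
REGIME_NEGLIGIBLE = "negligible"
REGIME_PARAMAGNETIC = "paramagnetic-slowed"
REGIME_NEAR_CRITICAL = "near-critical"
REGIME_SUPERCRITICAL = "supercritical"


@dataclass(frozen=True)
class BetaResult:
    """Dimensionless magnetic-to-thermal ratio with a qualitative regime tag."""

    beta: float
    regime: str


def _classify(b: float) -> str:
    if b > 1.0:
        return REGIME_SUPERCRITICAL
    if 0.95 <= b <= 1.0:
        return REGIME_NEAR_CRITICAL
    if b >= ONSET_BETA:
        return REGIME_PARAMAGNETIC
    if b <= -ONSET_BETA:
        return REGIME_DIAMAGNETIC
    return REGIME_NEGLIGIBLE


def beta(
    chi: float,
    field: FieldCondition,
    constants: PhysicalConstants = CONSTANTS,
) -> BetaResult:
    """Magnetic-to-thermal energy ratio beta = chi B^2 / (2 mu0 R T).

    Parameters
    ----------
    chi
        Molar magnetic susceptibility, m^3/mol, signed (negative for
        diamagnets).
    field
        Magnetic induction and temperature.

    Returns
    -------
    BetaResult
        ``beta`` carries the sign of chi; ``regime`` classifies it
        (supercritical above 1, near-critical in [0.95, 1], negligible
        below the 0.05 onset in magnitude).
    """
    if not field.T > 0:
        raise InvalidParameterError("temperature T must be > 0")
    b = chi * field.B**2 / (2.0 * constants.mu0 * constants.R_gas * field.T)
    return BetaResult(beta=b, regime=_classify(b))


def effective_diffusion(
    D: float,
    chi: float,
    field: FieldCondition,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Effective diffusion coefficient D_eff = D (1 - beta), m^2/s.

    May return a negative value when beta > 1 (supercritical squeezing);
    callers deciding dynamics must reject that regime themselves — the
    numeric solver does.
    """
    if not D > 0:
        raise InvalidParameterError("diffusion coefficient D must be > 0")
    return D * (1.0 - beta(chi, field, constants).beta)


def onset_field(
    chi: float,
    beta0: float = ONSET_BETA,
    T: float = 300.0,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Field B0 at which |beta| reaches beta0: B0 = sqrt(2 mu0 beta0 R T / |chi|).

    Defined through |chi| so it exists for diamagnets too (for them beta
    reaches -beta0 at B0).
    """
    if chi == 0:
        raise UndefinedOnsetError("onset field undefined for chi = 0")
    if not beta0 > 0:
        raise InvalidParameterError("beta0 must be > 0")
    if not T > 0:
        raise InvalidParameterError("temperature T must be > 0")
    return math.sqrt(2.0 * constants.mu0 * beta0 * constants.R_gas * T / abs(chi))


def critical_field(
    chi: float,
    T: float = 300.0,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Critical field B_cr = sqrt(2 mu0 R T / chi) where beta = 1 and D_eff = 0.

    Only paramagnetic diffusion can be suppressed, so chi must be positive.
    """
    if not chi > 0:
        raise NoCriticalFieldError(
            "critical field exists only for paramagnets (chi > 0); "
            "diamagnetic diffusion is never suppressed"
        )
    return onset_field(chi, 1.0, T, constants)


def force_density(
    chi: float,
    B: float,
    grad_n: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Concentration-gradient magnetic force density f = chi B^2 grad_n / (2 mu0), N/m^3."""
    return chi * B**2 * grad_n / (2.0 * constants.mu0)


def force_per_molecule(
    chi: float,
    B: float,
    n: float,
    grad_n: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Force per molecule f1 = chi B^2 grad_n / (2 mu0 n N_A), newton.

    ``n`` is the local molar concentration (mol/m^3); must be positive.
    """
    if not n > 0:
        raise InvalidParameterError("concentration n must be > 0")
    return force_density(chi, B, grad_n, constants) / (n * constants.N_A)


def drift_velocity(
    D: float,
    T: float,
    f1: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Drift speed u = gamma f1 with Nernst-Einstein mobility gamma = D / (k_B T), m/s."""
    if not D > 0:
        raise InvalidParameterError("diffusion coefficient D must be > 0")
    if not T > 0:
        raise InvalidParameterError("temperature T must be > 0")
    return D * f1 / (constants.k_B * T)


def magnetic_pressure(
    chi: float,
    R_c: float,
    B: float,
    grad_n: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Membrane pressure P = chi R_c B^2 grad_n / (6 mu0), pascal.

    The force density integrated over a spherical cell of radius ``R_c``
    divided by the membrane area: P = f V/S = f R_c / 3.
    """
    if not R_c > 0:
        raise InvalidParameterError("cell radius R_c must be > 0")
    return force_density(chi, B, grad_n, constants) * R_c / 3.0


def characteristic_time(L: float, D: float, beta_value: float = 0.0) -> float:
    """Characteristic diffusion time tau_eff = L^2 / (D (1 - beta)), seconds.

    Reduces to tau_0 = L^2/D at zero field; increased for paramagnets
    (0 < beta < 1), decreased for diamagnets (beta < 0).  Diverges as
    beta -> 1, so beta >= 1 raises :class:`DiffusionSuppressedError`.
    The relative change is (tau_eff - tau_0)/tau_0 = beta / (1 - beta).
    """
    if not D > 0:
        raise InvalidParameterError("diffusion coefficient D must be > 0")
    if beta_value >= 1.0:
        raise DiffusionSuppressedError(
            "beta >= 1: diffusion suppressed, characteristic time diverges"
        )
    return L**2 / (D * (1.0 - beta_value))


def gradient_force_ratio(gradB_over_B: float, n_over_gradn: float) -> float:
    """Ratio of the magnetic-gradient force to the concentration-gradient force.

    f_grad / f = 2 (grad B / B) (n / grad n): of order 1e-9 in an MRI bore,
    which is why only the concentration-gradient force is modelled.
    """
    if gradB_over_B < 0 or n_over_gradn < 0:
        raise InvalidParameterError("both ratio arguments must be >= 0")
    return 2.0 * gradB_over_B * n_over_gradn
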