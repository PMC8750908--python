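"""Composite biological scenarios: RBC gas exchange/swelling and drug diffusion.

Two report builders compose the closed-form calculators into the model's
biological applications:

* :func:`rbc_report` — oxygen and hemoglobin transport in a red blood cell.
  At zero field the characteristic times obey the hierarchy
  tau_ox (~10 ms) < Dt_trap (~10-100 ms) < tau_Hb (~1 s); a field slows the
  paramagnetic species (deoxyHb, O2), and the concentration-gradient force
  on the deoxyHb layer at the membrane produces an outward magnetic
  pressure P = chi R_c B^2 grad(n) / (6 mu0) that can swell a fully
  deoxygenated cell.  The pressure is judged against the 10-150 Pa range
  mitotic cells generate to round up — the only quantitative cellular
  pressure scale available for comparison.

* :func:`drug_report` — whether a given field measurably alters a
  registered paramagnetic agent's diffusion, via beta against the 0.05
  onset threshold.

Reports carry named scalars with units, qualitative flags from a fixed
vocabulary, and an echo of the inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from . import physics
from .physics import CONSTANTS, FieldCondition, PhysicalConstants, ONSET_BETA
from .species import get_species, HB_CONCENTRATION

__all__ = [
    "RBCParameters",
    "Quantity",
    "ScenarioReport",
    "MITOTIC_ROUNDING_PRESSURE_PA",
    "FLAG_TIME_HIERARCHY",
    "FLAG_SATURATION_RISK",
    "FLAG_SWELLING",
    "FLAG_SUPERCRITICAL",
    "FLAG_BELOW_ONSET",
    "FLAG_ABOVE_ONSET",
    "rbc_report",
    "drug_report",
    "nearest_power_of_ten",
]

#: Pressure band (Pa) mitotic HeLa cells exert while rounding to divide;
#: magnetic membrane pressure above its upper bound is flagged significant.
MITOTIC_ROUNDING_PRESSURE_PA = (10.0, 150.0)

FLAG_TIME_HIERARCHY = "time-hierarchy-held"
FLAG_SATURATION_RISK = "saturation-risk"
FLAG_SWELLING = "swelling-pressure-significant"
FLAG_SUPERCRITICAL = "supercritical"
FLAG_BELOW_ONSET = "below-onset"
FLAG_ABOVE_ONSET = "above-onset"


class Quantity(NamedTuple):
    value: float
    units: str


@dataclass(frozen=True)
class RBCParameters:
    """Red-blood-cell geometry, concentrations and time scales (SI).

    ``a`` is the diffusion length scale (cell radius) entering tau = a^2/D;
    ``R_c`` the mean cell radius used in the membrane-pressure estimate;
    ``trap_time_range`` the O2-trapping-by-Hb time window; and
    ``alveolar_transit`` the time an erythrocyte spends in a lung alveolus.
    """

    a: float = 3e-6
    R_c: float = 4e-6
    n_Hb: float = HB_CONCENTRATION
    D_Hb: float = 1.6e-11
    D_ox: float = 1e-9
    trap_time_range: tuple[float, float] = (0.01, 0.1)
    alveolar_transit: float = 0.8

    def __post_init__(self) -> None:
        positive = (self.a, self.R_c, self.n_Hb, self.D_Hb, self.D_ox,
                    *self.trap_time_range, self.alveolar_transit)
        if any(not v > 0 for v in positive):
            raise physics.InvalidParameterError("all RBC parameters must be positive")
        if self.trap_time_range[0] >= self.trap_time_range[1]:
            raise physics.InvalidParameterError("trap_time_range must be ascending")


@dataclass(frozen=True)
class ScenarioReport:
    """Named scalar results with units, qualitative flags, and input echo."""

    results: dict[str, Quantity]
    flags: tuple[str, ...]
    inputs: dict[str, float | str]

    def to_dict(self) -> dict:
        return {
            "results": {k: {"value": q.value, "units": q.units}
                        for k, q in self.results.items()},
            "flags": list(self.flags),
            "inputs": dict(self.inputs),
        }


def nearest_power_of_ten(x: float) -> float:
    """Round a positive quantity to the nearest power of ten (log-space)."""
    if not x > 0:
        raise physics.InvalidParameterError("argument must be positive")
    return 10.0 ** round(math.log10(x))


def rbc_report(
    B: float,
    T: float = 300.0,
    params: RBCParameters = RBCParameters(),
    constants: PhysicalConstants = CONSTANTS,
) -> ScenarioReport:
    """Field effect on RBC oxygen/hemoglobin transport and membrane pressure.

    Computes beta and D_eff for deoxyHb and O2 at (B, T); zero-field
    characteristic times tau_ox, tau_Hb and their field-modified values;
    and the magnetic membrane pressure for the fully deoxygenated cell with
    the volume-averaged gradient grad(n) = n_Hb / R_c.  Exact values are
    reported alongside their nearest-power-of-ten rough estimates.

    Flags: ``time-hierarchy-held`` when tau_ox,eff < trapping window <
    tau_Hb,eff; ``saturation-risk`` when tau_Hb,eff exceeds the alveolar
    transit time; ``swelling-pressure-significant`` when P_mag exceeds the
    mitotic rounding band; ``supercritical`` replaces the effective times
    when beta >= 1 for a species.
    """
    field = FieldCondition(B=B, T=T)
    hb = get_species("deoxyHb")
    o2 = get_species("O2")

    beta_hb = physics.beta(hb.chi_molar, field, constants).beta
    beta_o2 = physics.beta(o2.chi_molar, field, constants).beta

    tau_ox0 = physics.characteristic_time(params.a, params.D_ox, 0.0)
    tau_hb0 = physics.characteristic_time(params.a, params.D_Hb, 0.0)

    results: dict[str, Quantity] = {
        "beta_deoxyHb": Quantity(beta_hb, "dimensionless"),
        "beta_O2": Quantity(beta_o2, "dimensionless"),
        "tau_ox": Quantity(tau_ox0, "s"),
        "tau_ox_order": Quantity(nearest_power_of_ten(tau_ox0), "s"),
        "tau_Hb": Quantity(tau_hb0, "s"),
        "tau_Hb_order": Quantity(nearest_power_of_ten(tau_hb0), "s"),
    }
    flags: list[str] = []

    supercritical = beta_hb >= 1.0 or beta_o2 >= 1.0
    if supercritical:
        flags.append(FLAG_SUPERCRITICAL)
        tau_ox_eff = tau_hb_eff = None
    else:
        results["D_eff_deoxyHb"] = Quantity(params.D_Hb * (1.0 - beta_hb), "m^2/s")
        results["D_eff_O2"] = Quantity(params.D_ox * (1.0 - beta_o2), "m^2/s")
        tau_ox_eff = physics.characteristic_time(params.a, params.D_ox, beta_o2)
        tau_hb_eff = physics.characteristic_time(params.a, params.D_Hb, beta_hb)
        results["tau_ox_eff"] = Quantity(tau_ox_eff, "s")
        results["tau_Hb_eff"] = Quantity(tau_hb_eff, "s")

    p_mag = physics.magnetic_pressure(
        hb.chi_molar, params.R_c, B, params.n_Hb / params.R_c, constants
    )
    results["P_mag"] = Quantity(p_mag, "Pa")
    results["grad_n"] = Quantity(params.n_Hb / params.R_c, "mol/m^4")

    if tau_ox_eff is not None and tau_hb_eff is not None:
        lo, hi = params.trap_time_range
        if tau_ox_eff < lo and hi < tau_hb_eff:
            flags.append(FLAG_TIME_HIERARCHY)
        if tau_hb_eff > params.alveolar_transit:
            flags.append(FLAG_SATURATION_RISK)
    if p_mag > MITOTIC_ROUNDING_PRESSURE_PA[1]:
        flags.append(FLAG_SWELLING)

    inputs = {
        "B": B, "T": T, "a": params.a, "R_c": params.R_c,
        "n_Hb": params.n_Hb, "D_Hb": params.D_Hb, "D_ox": params.D_ox,
        "trap_time_lo": params.trap_time_range[0],
        "trap_time_hi": params.trap_time_range[1],
        "alveolar_transit": params.alveolar_transit,
    }
    return ScenarioReport(results=results, flags=tuple(flags), inputs=inputs)


def drug_report(
    species_name: str,
    B: float,
    T: float = 300.0,
    constants: PhysicalConstants = CONSTANTS,
) -> ScenarioReport:
    """Field effect on a registered agent's diffusion vs the onset threshold.

    Reports beta at (B, T), the onset field B0 at the 0.05 threshold, and
    the relative characteristic-time change beta / (1 - beta).  Flags
    ``below-onset`` when |beta| < 0.05 (equivalently B < B0: the field
    effect on the agent's diffusion is negligible), otherwise
    ``above-onset``; ``supercritical`` when beta >= 1.
    """
    sp = get_species(species_name)
    field = FieldCondition(B=B, T=T)
    b = physics.beta(sp.chi_molar, field, constants).beta
    b0_field = physics.onset_field(sp.chi_molar, ONSET_BETA, T, constants)

    results: dict[str, Quantity] = {
        "beta": Quantity(b, "dimensionless"),
        "onset_field_B0": Quantity(b0_field, "T"),
    }
    flags: list[str] = []
    if b >= 1.0:
        flags.append(FLAG_SUPERCRITICAL)
    else:
        results["relative_tau_change"] = Quantity(b / (1.0 - b), "dimensionless")
    flags.append(FLAG_BELOW_ONSET if abs(b) < ONSET_BETA else FLAG_ABOVE_ONSET)

    inputs = {"species": sp.name, "chi_molar": sp.chi_molar, "B": B, "T": T}
    return ScenarioReport(results=results, flags=tuple(flags), inputs=inputs)
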