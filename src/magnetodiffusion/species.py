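"""Registry of molar magnetic susceptibilities for biologically active molecules.

Ships the species whose onset fields the model tabulates — the three
hemoglobin states, molecular oxygen, and four paramagnetic agents used in
imaging and therapy — with signed SI molar susceptibilities (m^3/mol),
default diffusivities where the literature provides them, and provenance
notes.  Whole-cell red-blood-cell volume susceptibilities (a different
physical quantity, dimensionless SI) are kept as annotations only and are
not accepted by the molar-susceptibility calculators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable

import pandas as pd
import yaml

from .physics import CONSTANTS, PhysicalConstants, onset_field, ONSET_BETA

__all__ = [
    "MolecularSpecies",
    "OnsetTable",
    "SpeciesNotFoundError",
    "get_species",
    "list_species",
    "build_onset_table",
    "registry_to_yaml",
    "registry_from_yaml",
    "round_sig",
    "RBC_VOLUME_SUSCEPTIBILITY",
    "HB_CONCENTRATION",
]

#: Whole-cell RBC volume susceptibilities (SI, dimensionless), SQUID-measured.
#: Annotation only — not molar susceptibilities, not usable in beta().
RBC_VOLUME_SUSCEPTIBILITY = {
    "oxy RBC": -9.23e-6,
    "deoxy RBC": -5.72e-6,
    "met RBC": -5.27e-6,
}

#: Intracellular hemoglobin concentration, mol/m^3.
HB_CONCENTRATION = 5.5


class SpeciesNotFoundError(KeyError):
    """Requested species is not in the registry."""


@dataclass(frozen=True)
class MolecularSpecies:
    """One molecular species: susceptibility, optional diffusivity, provenance.

    ``chi_molar`` is the signed SI molar susceptibility in m^3/mol
    (negative = diamagnetic).  ``D_alternatives`` holds literature
    diffusivities other than the default.
    """

    name: str
    chi_molar: float
    D_default: float | None = None
    D_alternatives: tuple[float, ...] = ()
    molar_mass: float | None = None    # g/mol
    molar_volume: float | None = None  # mL/mol
    notes: str = ""
    aliases: tuple[str, ...] = ()
    in_onset_table: bool = True

    def __post_init__(self) -> None:
        if self.chi_molar == 0:
            raise ValueError("chi_molar must be nonzero")

    @property
    def diamagnetic(self) -> bool:
        return self.chi_molar < 0


# The larger hemoglobin diffusivity is the default: the tau_Hb ~ 1 s
# characteristic-time estimate is built on it.
_SPECIES: tuple[MolecularSpecies, ...] = (
    MolecularSpecies(
        name="deoxyHb",
        chi_molar=+60.4e-8,
        D_default=1.6e-11,
        D_alternatives=(3.4e-12,),
        molar_mass=64450.0,
        molar_volume=48277.0,
        notes=(
            "Deoxygenated hemoglobin, paramagnetic. Two literature "
            "diffusivities are in circulation (1.6e-11 and 3.4e-12 m^2/s); "
            "the larger is the default."
        ),
        aliases=("deoxyhemoglobin", "deoxyhaemoglobin", "hb"),
    ),
    MolecularSpecies(
        name="metHb",
        chi_molar=+7.217e-7,
        molar_mass=64450.0,
        notes="Methemoglobin (ferric iron), paramagnetic.",
        aliases=("methemoglobin", "methaemoglobin"),
    ),
    MolecularSpecies(
        name="oxyHb",
        chi_molar=-4.754e-7,
        molar_mass=64450.0,
        notes="Oxygenated hemoglobin, diamagnetic (SI molar convention).",
        aliases=("oxyhemoglobin", "oxyhaemoglobin"),
    ),
    MolecularSpecies(
        name="O2",
        chi_molar=+4.3e-8,
        D_default=1e-9,
        notes="Molecular oxygen, paramagnetic; diffusivity inside an RBC.",
        aliases=("oxygen", "o₂"),
    ),
    MolecularSpecies(
        name="Gd",
        chi_molar=+18.5e-8,
        notes="Gadolinium(III) MRI contrast ion, paramagnetic.",
        aliases=("gadolinium", "gd(iii)", "gd3+"),
    ),
    MolecularSpecies(
        name="FeCl3",
        chi_molar=+2.573e-8,
        notes=(
            "Ferric chloride, paramagnetic; used to induce arterial "
            "thrombosis. A smaller value +1.345e-8 m^3/mol also appears in "
            "the literature; the tabulated value is kept."
        ),
        aliases=("ferric chloride", "iron(iii) chloride"),
    ),
    MolecularSpecies(
        name="MnCl2",
        chi_molar=+3.8e-8,
        notes="Manganese chloride, paramagnetic nutraceutical / MRI contrast.",
        aliases=("manganese chloride",),
    ),
    MolecularSpecies(
        name="Ho(NO3)3",
        chi_molar=+11.34e-8,
        notes="Holmium nitrate, paramagnetic; intratumoural radiotherapy agent.",
        aliases=("holmium nitrate", "ho(no₃)₃", "honitrate"),
    ),
)


def _build_index(species: Iterable[MolecularSpecies]) -> dict[str, MolecularSpecies]:
    index: dict[str, MolecularSpecies] = {}
    for sp in species:
        for key in (sp.name, *sp.aliases):
            index[key.lower()] = sp
    return index


_INDEX = _build_index(_SPECIES)


def list_species() -> tuple[MolecularSpecies, ...]:
    """All registered species in registry order."""
    return _SPECIES


def get_species(name: str) -> MolecularSpecies:
    """Case-insensitive lookup by canonical name or alias."""
    try:
        return _INDEX[name.strip().lower()]
    except KeyError:
        available = ", ".join(sp.name for sp in _SPECIES)
        raise SpeciesNotFoundError(
            f"unknown species {name!r}; available: {available}"
        ) from None


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 passes through)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class OnsetTable:
    """Per-species onset fields B0 at a given threshold beta0 and temperature."""

    beta0: float
    T: float
    rows: tuple[tuple[str, float, float], ...] = dc_field(default_factory=tuple)
    # each row: (species name, chi_molar m^3/mol, B0 tesla at 3 s.f.)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["species", "chi_m3_per_mol", "B0_T"]
        )


def build_onset_table(
    beta0: float = ONSET_BETA,
    T: float = 300.0,
    constants: PhysicalConstants = CONSTANTS,
) -> OnsetTable:
    """Onset field B0 = sqrt(2 mu0 beta0 R T / |chi|) for every tabulated species.

    Fields are reported at 3 significant figures, the precision the
    quantity is meaningful to given the susceptibility data.
    """
    rows = tuple(
        (sp.name, sp.chi_molar, round_sig(onset_field(sp.chi_molar, beta0, T, constants), 3))
        for sp in _SPECIES
        if sp.in_onset_table
    )
    return OnsetTable(beta0=beta0, T=T, rows=rows)


def registry_to_yaml() -> str:
    """Serialize the registry to the human-editable config dialect (YAML)."""
    payload = [
        {
            "name": sp.name,
            "chi_molar": sp.chi_molar,
            "D_default": sp.D_default,
            "D_alternatives": list(sp.D_alternatives),
            "molar_mass": sp.molar_mass,
            "molar_volume": sp.molar_volume,
            "notes": sp.notes,
            "aliases": list(sp.aliases),
            "in_onset_table": sp.in_onset_table,
        }
        for sp in _SPECIES
    ]
    return yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)


def registry_from_yaml(text: str) -> tuple[MolecularSpecies, ...]:
    """Reload species records serialized by :func:`registry_to_yaml`."""
    payload = yaml.safe_load(text)
    return tuple(
        MolecularSpecies(
            name=item["name"],
            chi_molar=item["chi_molar"],
            D_default=item.get("D_default"),
            D_alternatives=tuple(item.get("D_alternatives") or ()),
            molar_mass=item.get("molar_mass"),
            molar_volume=item.get("molar_volume"),
            notes=item.get("notes", ""),
            aliases=tuple(item.get("aliases") or ()),
            in_onset_table=item.get("in_onset_table", True),
        )
        for item in payload
    )
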