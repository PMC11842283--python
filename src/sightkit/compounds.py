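"""Registry of compound and growth-medium physical constants.

Every quantity in this module carries a fixed unit; no unit strings are
parsed.  ``Compound`` records hold the constants needed by the closed-vial
partitioning model: molar mass (g mol^-1), neat-liquid density (g cm^-3),
the dimensionless air/medium partition coefficient (concentration in the
headspace gas divided by concentration in the aqueous medium, at the
reference temperature), and the aqueous solubility limit (mmol L^-1).

The bundled default is styrene: k_air/medium = 0.148 at 30 degC and a
solubility limit of 2.8 mM.  Molar mass (104.15 g mol^-1) and density
(0.906 g cm^-3 near room temperature) are standard CRC-handbook reference
values.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

from .errors import DomainError, UnknownCompoundError

__all__ = [
    "Compound",
    "MediumSpec",
    "STYRENE",
    "get_compound",
    "register_compound",
    "registered_names",
    "load_registry",
    "dump_registry",
]


@dataclass(frozen=True)
class Compound:
    """Physicochemical constants of a volatile solvent.

    Parameters
    ----------
    name:
        Registry key; lookup is case-insensitive.
    molar_mass:
        g mol^-1, must be positive.
    density:
        Neat-liquid density in g cm^-3, must be positive.
    k_air_medium:
        Dimensionless concentration ratio c_air / c_medium at
        ``k_reference_temp``.  Treated as temperature-independent; callers
        are warned when the system temperature deviates by more than 2 degC.
    solubility_limit:
        Aqueous solubility in mmol L^-1; dosing beyond it forms a neat
        organic phase.
    k_reference_temp:
        degC at which ``k_air_medium`` was determined.
    logP_ow:
        Octanol/water log partition coefficient.  Informational only
        (compounds with logP 1.5-4 are broadly cytotoxic to microbes).
    """

    name: str
    molar_mass: float
    density: float
    k_air_medium: float
    solubility_limit: float
    k_reference_temp: float = 30.0
    logP_ow: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise DomainError(f"molar_mass must be > 0, got {self.molar_mass}")
        if self.density <= 0:
            raise DomainError(f"density must be > 0, got {self.density}")
        if self.k_air_medium < 0:
            raise DomainError(f"k_air_medium must be >= 0, got {self.k_air_medium}")
        if self.solubility_limit <= 0:
            raise DomainError(
                f"solubility_limit must be > 0, got {self.solubility_limit}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("name")
        return d

    @classmethod
    def from_dict(cls, name: str, record: dict) -> "Compound":
        return cls(name=name, **record)


@dataclass(frozen=True)
class MediumSpec:
    """Growth-medium composition relevant to the closed-vial budgets.

    glucose_conc is mmol L^-1; o2_solubility is the dissolved-oxygen
    saturation in mg L^-1 at the preparation temperature (9.1 mg L^-1 at
    20 degC for the default mineral salt medium).
    """

    glucose_conc: float = 20.0
    o2_solubility: float = 9.1

    def __post_init__(self) -> None:
        if self.glucose_conc < 0:
            raise DomainError(f"glucose_conc must be >= 0, got {self.glucose_conc}")
        if self.o2_solubility < 0:
            raise DomainError(f"o2_solubility must be >= 0, got {self.o2_solubility}")


#: Bundled styrene record.  k_air/medium and the 2.8 mM solubility limit are
#: literature values at 30 degC; molar mass and density are CRC reference
#: constants; logP octanol/water = 3.05.
STYRENE = Compound(
    name="styrene",
    molar_mass=104.15,
    density=0.906,
    k_air_medium=0.148,
    solubility_limit=2.8,
    k_reference_temp=30.0,
    logP_ow=3.05,
)

_REGISTRY: dict[str, Compound] = {STYRENE.name: STYRENE}


def registered_names() -> list[str]:
    """Names currently in the registry, sorted for deterministic output."""
    return sorted(_REGISTRY)


def register_compound(compound: Compound, overwrite: bool = False) -> None:
    key = compound.name.strip().lower()
    if key in _REGISTRY and not overwrite:
        raise DomainError(f"compound {key!r} already registered")
    _REGISTRY[key] = replace(compound, name=key)


def get_compound(name: str) -> Compound:
    """Look up a compound by name (case-insensitive).

    Raises
    ------
    UnknownCompoundError
        If the name is not registered; the message lists registered names.
    """
    key = name.strip().lower()
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownCompoundError(
            f"unknown compound {name!r}; registered: {', '.join(registered_names())}"
        ) from None


def load_registry(path: str | Path) -> dict[str, Compound]:
    """Read a YAML registry file and register every record it contains.

    The file maps compound name to a mapping of the ``Compound`` fields
    (without ``name``).  Returns the newly loaded compounds.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    loaded = {}
    for name, record in raw.items():
        compound = Compound.from_dict(str(name).strip().lower(), record)
        register_compound(compound, overwrite=True)
        loaded[compound.name] = compound
    return loaded


def dump_registry(path: str | Path, compounds: list[Compound] | None = None) -> None:
    """Write compounds (default: the whole registry) to a YAML file."""
    if compounds is None:
        compounds = list(_REGISTRY.values())
    payload = {c.name: c.to_dict() for c in compounds}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
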