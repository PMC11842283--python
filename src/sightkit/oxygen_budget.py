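"""Oxygen supply versus carbon-source demand in a sealed vial.

A hermetically closed vial receives oxygen only once: the headspace gas
present at sealing plus the oxygen dissolved in the medium.  The headspace
term follows the ideal-gas law, n = P * V_a * x_O2 / (R * T), evaluated at
the *preparation* conditions (20 degC, 101.3 kPa by default — sealing
happens on the bench, not in the incubator).  The dissolved term is the
saturation solubility of the medium (mg L^-1) times the fill volume.

Demand side: complete oxidation of glucose consumes six moles of O2 per
mole (C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O).  With a biomass yield Y_X/S
(g cell dry weight per g glucose), the yield is interpreted as the mass
fraction of glucose routed to biomass and the remainder is fully oxidized:

    n_O2_demand = n_glucose * (1 - Y_X/S) * 6.

For the default condition (4.937 mL vial, 600 uL of 20 mM glucose medium,
Y_X/S = 0.396) this gives 43.5 umol demand against 38.0 umol supply, i.e.
oxygen — not glucose — limits the culture.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .compounds import MediumSpec
from .errors import DomainError
from .partition import VialSystem

__all__ = [
    "R_GAS",
    "O2_MOLAR_MASS",
    "O2_PER_GLUCOSE",
    "OxygenSupply",
    "OxygenGlucoseBudget",
    "oxygen_supply",
    "glucose_inventory",
    "oxidizable_glucose",
    "oxygen_demand",
    "classify_limitation",
]

R_GAS = 8.314  # J mol^-1 K^-1
O2_MOLAR_MASS = 32.0  # g mol^-1
O2_PER_GLUCOSE = 6.0  # mol O2 per mol glucose, complete oxidation


class OxygenSupply(NamedTuple):
    n_o2_headspace: float  # umol
    n_o2_dissolved: float  # umol
    n_o2_total: float  # umol


@dataclass(frozen=True)
class OxygenGlucoseBudget:
    """Full supply/demand accounting for one vial. All amounts in umol."""

    n_o2_headspace: float
    n_o2_dissolved: float
    n_o2_total: float
    n_glucose: float
    n_glucose_oxidizable: float
    biomass_yield: float
    n_o2_demand: float
    limiting_factor: str  # "oxygen" | "carbon" | "balanced"

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def oxygen_supply(
    system: VialSystem,
    medium: MediumSpec,
    o2_fraction: float = 0.21,
    prep_temperature: float = 20.0,
    include_dissolved: bool = True,
) -> OxygenSupply:
    """Total oxygen sealed into the vial, in umol.

    Headspace term: ideal gas at the preparation temperature and the
    system pressure.  Dissolved term: ``o2_solubility`` (mg L^-1 at the
    preparation temperature) times the fill volume; it contributes only
    ~0.2 umol for a 600 uL fill but is included by default
    (``include_dissolved=False`` drops it).
    """
    if prep_temperature <= -273.15:
        raise DomainError(f"non-physical temperature {prep_temperature} degC")
    if not 0 <= o2_fraction <= 1:
        raise DomainError(f"o2_fraction must be in [0, 1], got {o2_fraction}")

    p_pa = system.pressure * 1e3
    v_a_m3 = system.v_air * 1e-6  # mL -> m^3
    t_k = prep_temperature + 273.15
    n_head_mol = p_pa * v_a_m3 * o2_fraction / (R_GAS * t_k)
    n_head = n_head_mol * 1e6  # umol

    n_diss = 0.0
    if include_dissolved:
        mass_mg = medium.o2_solubility * system.v_medium * 1e-3  # mg/L * L
        n_diss = mass_mg / O2_MOLAR_MASS * 1e3  # mmol -> umol

    return OxygenSupply(n_head, n_diss, n_head + n_diss)


def glucose_inventory(system: VialSystem, medium: MediumSpec) -> float:
    """Glucose sealed into the vial, umol: concentration times fill volume."""
    return medium.glucose_conc * system.v_medium  # mM * mL = umol


def oxidizable_glucose(n_o2_total: float) -> float:
    """Glucose (umol) fully oxidizable by ``n_o2_total`` umol O2, no biomass."""
    if n_o2_total < 0:
        raise DomainError(f"n_o2_total must be >= 0, got {n_o2_total}")
    return n_o2_total / O2_PER_GLUCOSE


def oxygen_demand(n_glucose: float, biomass_yield: float) -> float:
    """Yield-corrected oxygen demand (umol) for complete glucose consumption.

    ``biomass_yield`` (Y_X/S, g CDW per g glucose) is read as the mass
    fraction of glucose routed into biomass; the remaining fraction is
    fully oxidized at 6 mol O2 per mol glucose.
    """
    if not 0 <= biomass_yield < 1:
        raise DomainError(f"biomass_yield must be in [0, 1), got {biomass_yield}")
    if n_glucose < 0:
        raise DomainError(f"n_glucose must be >= 0, got {n_glucose}")
    return n_glucose * (1.0 - biomass_yield) * O2_PER_GLUCOSE


def classify_limitation(
    system: VialSystem,
    medium: MediumSpec,
    biomass_yield: float = 0.396,
    o2_fraction: float = 0.21,
    prep_temperature: float = 20.0,
    include_dissolved: bool = True,
    balance_tolerance: float = 0.01,
) -> OxygenGlucoseBudget:
    """Assemble the full budget and identify the limiting substrate.

    The factor is "oxygen" when demand exceeds supply, "carbon" when supply
    exceeds demand, and "balanced" when the two agree within
    ``balance_tolerance`` (relative, default 1%).  All comparisons use full
    precision; round only for display.
    """
    supply = oxygen_supply(
        system, medium, o2_fraction, prep_temperature, include_dissolved
    )
    n_glc = glucose_inventory(system, medium)
    demand = oxygen_demand(n_glc, biomass_yield)

    if supply.n_o2_total > 0 and abs(demand - supply.n_o2_total) <= (
        balance_tolerance * supply.n_o2_total
    ):
        limiting = "balanced"
    elif demand > supply.n_o2_total:
        limiting = "oxygen"
    else:
        limiting = "carbon"

    return OxygenGlucoseBudget(
        n_o2_headspace=supply.n_o2_headspace,
        n_o2_dissolved=supply.n_o2_dissolved,
        n_o2_total=supply.n_o2_total,
        n_glucose=n_glc,
        n_glucose_oxidizable=oxidizable_glucose(supply.n_o2_total),
        biomass_yield=biomass_yield,
        n_o2_demand=demand,
        limiting_factor=limiting,
    )
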