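"""Closed-system gas/liquid/organic partitioning of a volatile solvent.

A sealed vial holds an aqueous medium of volume V_m and a headspace of
volume V_a = V_total - V_m.  At equilibrium a volatile solute distributes
between the two phases according to a dimensionless partition coefficient
k = c_air / c_medium.  Writing n for the total amount of solute, mass
balance gives

    n = c_m * V_m + c_a * V_a = c_m * (V_m + k * V_a)

so below saturation

    c_m = n / (V_m * (1 + k * V_a / V_m)).

Inverting for the volume of neat solvent that produces a target aqueous
concentration c_m:

    V_solvent = V_m * (1 + k * V_a / V_m) * c_m * M / rho,

with M the molar mass and rho the neat-liquid density.  Once c_m reaches
the aqueous solubility limit, any further solvent forms a neat organic
phase: the aqueous phase is capped at the limit, the headspace follows
c_a = k * c_limit, and the excess is reported as the organic-phase amount.

The volume occupied by the dosed solvent itself is neglected (doses are
sub-uL to few-uL against multi-mL phase volumes), and k is given directly
as a concentration ratio so no ideal-gas conversion is involved.
Internally all arithmetic is done in mol, L, and g; umol, mM, and uL
appear only at the interface.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .compounds import Compound
from .errors import DomainError, SaturationError

__all__ = [
    "VialSystem",
    "PartitionState",
    "SecondPhaseDose",
    "equilibrate",
    "dose_for_target",
    "second_phase_dose",
]

# Interface <-> internal conversions
_ML_TO_L = 1e-3
_UL_TO_CM3 = 1e-3  # 1 uL = 1e-3 cm^3
_CM3_TO_UL = 1e3
_MM_TO_M = 1e-3  # mmol/L -> mol/L
_MOL_TO_UMOL = 1e6

# Relative tolerance deciding whether an organic phase is present; a dose
# landing exactly on the saturation capacity is classified as saturated
# aqueous phase without a second phase.
_ORGANIC_RTOL = 1e-12


@dataclass(frozen=True)
class VialSystem:
    """Geometry and ambient conditions of one sealed vial.

    v_total and v_medium are in mL, temperature in degC, pressure in kPa.
    The defaults describe a commercial nominal-5-mL screw-cap vial whose
    measured total volume is 4.937 mL, filled with 600 uL of medium and
    incubated at 30 degC under ambient pressure.
    """

    v_total: float = 4.937
    v_medium: float = 0.600
    temperature: float = 30.0
    pressure: float = 101.3

    def __post_init__(self) -> None:
        if not 0 < self.v_medium < self.v_total:
            raise DomainError(
                f"require 0 < v_medium < v_total, got v_medium={self.v_medium}, "
                f"v_total={self.v_total}"
            )
        if self.temperature <= -273.15:
            raise DomainError(f"non-physical temperature {self.temperature} degC")
        if self.pressure <= 0:
            raise DomainError(f"pressure must be > 0, got {self.pressure}")

    @property
    def v_air(self) -> float:
        """Headspace volume in mL (strictly positive by construction)."""
        return self.v_total - self.v_medium


@dataclass(frozen=True)
class PartitionState:
    """Equilibrium distribution of the solvent across the three phases.

    Amounts are umol, concentrations mmol L^-1, organic-phase volume uL.
    ``c_air`` is the concentration in the headspace gas referred to the
    headspace volume.  ``n_medium + n_air + n_organic == n_total`` holds to
    a relative tolerance of 1e-9, and ``c_medium`` never exceeds the
    compound's solubility limit.
    """

    n_total: float
    c_medium: float
    c_air: float
    n_medium: float
    n_air: float
    n_organic: float
    organic_phase_present: bool
    v_organic: float

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass(frozen=True)
class SecondPhaseDose:
    """A %-v/v dose that deliberately overshoots the solubility limit."""

    volume_ul: float
    #: The aqueous phase will sit at the solubility limit once equilibrated.
    aqueous_saturated: bool = True
    #: True when the volume is within 5% of the single-phase saturation dose
    #: (only evaluated when a compound was supplied).
    near_saturation_dose: bool | None = None


def _warn_if_temperature_mismatch(system: VialSystem, compound: Compound) -> None:
    if abs(system.temperature - compound.k_reference_temp) > 2.0:
        warnings.warn(
            f"k_air_medium for {compound.name!r} was determined at "
            f"{compound.k_reference_temp} degC but the system is at "
            f"{system.temperature} degC; the partition coefficient is applied "
            "without temperature correction",
            stacklevel=3,
        )


def _effective_volume_l(system: VialSystem, compound: Compound) -> float:
    """V_m + k * V_a in litres — the denominator of the mass balance."""
    v_m = system.v_medium * _ML_TO_L
    v_a = system.v_air * _ML_TO_L
    return v_m + compound.k_air_medium * v_a


def equilibrate(
    dose_volume: float, system: VialSystem, compound: Compound
) -> PartitionState:
    """Distribute a neat-solvent dose (uL) across medium, headspace, organic.

    Below saturation the aqueous concentration is
    ``n / (V_m * (1 + k * V_a / V_m))``; above it the aqueous phase is
    capped at the solubility limit and the excess is routed to a neat
    organic phase.  Mass is conserved exactly.
    """
    if dose_volume < 0:
        raise DomainError(f"dose_volume must be >= 0, got {dose_volume}")
    _warn_if_temperature_mismatch(system, compound)

    n_total = compound.density * dose_volume * _UL_TO_CM3 / compound.molar_mass  # mol
    v_m = system.v_medium * _ML_TO_L
    v_a = system.v_air * _ML_TO_L
    k = compound.k_air_medium
    v_eff = _effective_volume_l(system, compound)

    c_sat = compound.solubility_limit * _MM_TO_M  # mol/L
    n_capacity = c_sat * v_eff  # mol held at saturation without organic phase

    if n_total <= n_capacity * (1.0 + _ORGANIC_RTOL):
        c_m = n_total / v_eff if n_total > 0 else 0.0
        n_organic = 0.0
    else:
        c_m = c_sat
        n_organic = n_total - n_capacity

    c_a = k * c_m
    n_m = c_m * v_m
    n_a = c_a * v_a
    organic_present = n_organic > _ORGANIC_RTOL * max(n_total, 1e-300)
    v_organic_ul = n_organic * compound.molar_mass / compound.density * _CM3_TO_UL

    return PartitionState(
        n_total=n_total * _MOL_TO_UMOL,
        c_medium=c_m / _MM_TO_M,
        c_air=c_a / _MM_TO_M,
        n_medium=n_m * _MOL_TO_UMOL,
        n_air=n_a * _MOL_TO_UMOL,
        n_organic=n_organic * _MOL_TO_UMOL,
        organic_phase_present=organic_present,
        v_organic=v_organic_ul,
    )


def dose_for_target(
    c_target: float, system: VialSystem, compound: Compound
) -> float:
    """Neat-solvent volume (uL) that equilibrates to ``c_target`` mM aqueous.

    Inverse of :func:`equilibrate` on ``[0, solubility_limit]``; the round
    trip reproduces the target to better than 1e-9 relative error.

    Raises
    ------
    SaturationError
        If ``c_target`` exceeds the solubility limit — dose a second phase
        by volume fraction (:func:`second_phase_dose`) instead.
    """
    if c_target < 0:
        raise DomainError(f"c_target must be >= 0, got {c_target}")
    if c_target > compound.solubility_limit * (1.0 + 1e-12):
        raise SaturationError(
            f"target {c_target} mM exceeds the solubility limit of "
            f"{compound.solubility_limit} mM for {compound.name!r}; above the "
            "limit the aqueous phase saturates — dose a second phase by "
            "volume fraction (second_phase_dose) instead"
        )
    _warn_if_temperature_mismatch(system, compound)

    n_needed = c_target * _MM_TO_M * _effective_volume_l(system, compound)  # mol
    volume_cm3 = n_needed * compound.molar_mass / compound.density
    return volume_cm3 * _CM3_TO_UL


def second_phase_dose(
    fraction_v_v: float,
    system: VialSystem,
    compound: Compound | None = None,
) -> SecondPhaseDose:
    """Volume (uL) corresponding to a %-v/v addition relative to the medium.

    Used once the concentration ramp has reached the solubility limit: the
    returned dose deliberately exceeds the aqueous capacity, so the aqueous
    phase will sit at the solubility limit and the remainder forms a neat
    organic phase.  When a compound is supplied, the result also notes
    whether the dose happens to fall within 5% of the single-phase
    saturation dose.
    """
    if fraction_v_v <= 0:
        raise DomainError(f"fraction_v_v must be > 0, got {fraction_v_v}")
    volume_ul = fraction_v_v / 100.0 * system.v_medium * 1e3  # mL -> uL
    near = None
    if compound is not None:
        sat_dose = dose_for_target(compound.solubility_limit, system, compound)
        near = abs(volume_ul - sat_dose) <= 0.05 * sat_dose
    return SecondPhaseDose(volume_ul=volume_ul, near_saturation_dose=near)
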