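"""Stepwise solvent-ramp planning for tolerance adaptive laboratory evolution.

The ramp starts at an aqueous target concentration and rises by a fixed
increment each cultivation cycle.  Once the next target would exceed the
aqueous solubility limit, the schedule switches to "second phase" mode:
the solvent is dosed as a volume fraction of the medium (1% v/v by
default), which saturates the aqueous phase and leaves a neat organic
layer, holding the selection pressure at its maximum.  Each cycle carries
the neat-solvent dose volume computed from the closed-system partitioning
model, and the inoculation density for the transfer.

Whether a cycle exactly at the solubility limit is run before switching is
a design choice: by default targets strictly above the limit trigger the
switch (for the styrene defaults, 2.75 mM is the last aqueous cycle and
cycle 9 is the first second-phase cycle); ``include_saturation_cycle``
inserts an explicit cycle at the limit first.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .compounds import Compound, STYRENE
from .errors import DomainError
from .partition import VialSystem, dose_for_target, second_phase_dose

__all__ = ["ALECycle", "ALESchedule", "build_schedule"]

_TOL = 1e-9


@dataclass(frozen=True)
class ALECycle:
    """One cultivation cycle of the ramp.

    ``c_target`` (mM) is set in aqueous mode, ``fraction_v_v`` (% v/v) in
    second-phase mode; the other is None.  ``dose_volume`` is uL of neat
    solvent.
    """

    index: int
    mode: str  # "aqueous" | "second_phase"
    dose_volume: float
    c_target: float | None = None
    fraction_v_v: float | None = None
    inoculum_od: float = 0.05


@dataclass
class ALESchedule:
    cycles: list[ALECycle] = field(default_factory=list)
    #: True when the requested start already exceeded the solubility limit,
    #: so every cycle runs in second-phase mode.
    all_second_phase: bool = False

    @property
    def first_second_phase_index(self) -> int | None:
        for cycle in self.cycles:
            if cycle.mode == "second_phase":
                return cycle.index
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": [c.index for c in self.cycles],
                "mode": [c.mode for c in self.cycles],
                "target_mM": [c.c_target for c in self.cycles],
                "fraction_v_v": [c.fraction_v_v for c in self.cycles],
                "dose_ul": [c.dose_volume for c in self.cycles],
                "inoculum_od": [c.inoculum_od for c in self.cycles],
            }
        )


def build_schedule(
    c_start: float = 1.0,
    increment: float = 0.25,
    compound: Compound = STYRENE,
    system: VialSystem | None = None,
    second_phase_fraction: float = 1.0,
    n_second_phase_cycles: int = 2,
    include_saturation_cycle: bool = False,
    inoculum_od: float = 0.05,
) -> ALESchedule:
    """Build the concentration-ramp schedule.

    Aqueous cycles run at ``c_start + (i - 1) * increment`` for every value
    not exceeding the compound's solubility limit; the ramp then continues
    with ``n_second_phase_cycles`` second-phase cycles at
    ``second_phase_fraction`` % v/v.  A start above the limit produces an
    all-second-phase schedule (flagged, not an error).
    """
    if c_start <= 0:
        raise DomainError(f"c_start must be > 0, got {c_start}")
    if increment <= 0:
        raise DomainError(f"increment must be > 0, got {increment}")
    if n_second_phase_cycles < 0:
        raise DomainError(
            f"n_second_phase_cycles must be >= 0, got {n_second_phase_cycles}"
        )
    if system is None:
        system = VialSystem()

    limit = compound.solubility_limit
    schedule = ALESchedule()
    index = 1

    if c_start > limit + _TOL:
        schedule.all_second_phase = True
        warnings.warn(
            f"c_start={c_start} mM exceeds the solubility limit of {limit} mM; "
            "the schedule is entirely second-phase",
            stacklevel=2,
        )
        if n_second_phase_cycles == 0:
            n_second_phase_cycles = 1  # a schedule must contain something
    else:
        i = 0
        last_target = None
        while True:
            target = c_start + i * increment
            if target > limit + _TOL:
                break
            schedule.cycles.append(
                ALECycle(
                    index=index,
                    mode="aqueous",
                    c_target=target,
                    dose_volume=dose_for_target(target, system, compound),
                    inoculum_od=inoculum_od,
                )
            )
            last_target = target
            index += 1
            i += 1
        if include_saturation_cycle and (
            last_target is None or last_target < limit - _TOL
        ):
            schedule.cycles.append(
                ALECycle(
                    index=index,
                    mode="aqueous",
                    c_target=limit,
                    dose_volume=dose_for_target(limit, system, compound),
                    inoculum_od=inoculum_od,
                )
            )
            index += 1

    for _ in range(n_second_phase_cycles):
        dose = second_phase_dose(second_phase_fraction, system, compound)
        schedule.cycles.append(
            ALECycle(
                index=index,
                mode="second_phase",
                fraction_v_v=second_phase_fraction,
                dose_volume=dose.volume_ul,
                inoculum_od=inoculum_od,
            )
        )
        index += 1

    return schedule
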