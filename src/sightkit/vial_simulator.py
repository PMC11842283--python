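"""Synthetic closed-vial growth simulator.

Generates biomass, glucose, dissolved- and headspace-oxygen, and Green-
Value trajectories for a sealed vial, so the growth-analysis and budget
machinery can be exercised end-to-end without an instrument.  The model is
phenomenological: it is parameterized to reproduce the qualitative closed-
vial behaviours (complete glucose consumption without solvent stress,
residual glucose under a second styrene phase, earlier oxygen limitation
at higher fill volumes, dose-dependent lag and growth-rate depression) —
not to fit any measured kinetics.

Model
-----
Biomass (latent OD600 ``X``) grows at

    mu = mu_max * S/(Ks + S) * DO/(Ko + DO) * 1/(1 + c_sty/IC50)

with growth suppressed until ``t > lag_per_mM * c_sty``.  Glucose is
consumed at (dX/dt)/Y_eff where the effective yield ``Y_eff = Y * f_sty``
falls with solvent stress (stressed cells divert substrate from biomass
to maintenance respiration).  Oxygen is drawn from a dissolved pool at

    OUR = 6 * (1 - Y_eff) * eta * (glucose consumption rate)

where ``eta`` (default 0.85) is a respiratory-efficiency factor modelling
the flexible Pseudomonas electron-transport chain, which lets the default
non-stress condition finish its glucose within the ~38 umol sealed-in
oxygen even though the naive stoichiometric demand slightly exceeds it.
The dissolved pool is replenished from the headspace at a volumetric
transfer coefficient kLa scaled inversely with fill depth (taller liquid
column, slower transfer), with the saturation level proportional to the
remaining headspace oxygen.  The dissolved-oxygen balance is integrated
semi-implicitly so stiff transfer dynamics stay stable at the default
step size; biomass uses an exponential (Rosenbrock-free) update.

The solvent concentration is held at its equilibrium value from the
partitioning model for the whole run (the organism does not degrade it).
The observed Green Value is the inverse linear calibration transform of
the latent OD plus seeded additive Gaussian noise; OD itself is never
observed.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import Compound, MediumSpec, STYRENE
from .errors import DomainError, LayoutError, StepSizeError
from .growth_analysis import BLANK_CONDITION
from .oxygen_budget import O2_MOLAR_MASS, O2_PER_GLUCOSE, oxygen_supply
from .partition import VialSystem, equilibrate

__all__ = [
    "SimulationParams",
    "SimulatedVial",
    "WellSpec",
    "simulate",
    "simulate_plate",
    "GLUCOSE_MOLAR_MASS",
]

GLUCOSE_MOLAR_MASS = 180.16  # g mol^-1

_WELL_RE = re.compile(r"^[A-D][1-6]$")
_MAX_WELLS = 24
_BALANCE_RTOL = 1e-6


@dataclass(frozen=True)
class SimulationParams:
    """Tunable parameters of the closed-vial model.

    Rates are h^-1, concentrations mM, yields g CDW per g glucose.  The
    defaults emulate a glucose-grown Pseudomonas culture in a sealed
    5 mL vial: mu_max 0.6 h^-1, Y_X/S 0.396, kLa 100 h^-1 at the 600 uL
    reference fill (shaken sub-mL culture), styrene IC50 1 mM on the
    growth rate, and 1.5 h of extra lag per mM of dissolved styrene.  The
    Green-Value transform inverts the linear OD calibration
    (od = gv_slope * gv + gv_intercept) and adds Gaussian noise of
    ``noise_sd`` GV units.
    """

    mu_max: float = 0.6
    ks_glucose: float = 0.05
    yield_biomass: float = 0.396
    o2_per_glucose: float = O2_PER_GLUCOSE
    o2_efficiency: float = 0.85
    ko_o2: float = 0.003
    kla0: float = 100.0
    kla_reference_fill: float = 0.6  # mL
    inhibition_ic50: float = 1.0
    lag_per_mM: float = 1.5
    od0: float = 0.05
    od_to_cdw: float = 0.4  # g CDW L^-1 per OD600 unit
    gv_slope: float = 0.078
    gv_intercept: float = -2.412
    noise_sd: float = 0.5
    dt: float = 0.05
    t_end: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "o2_per_glucose": self.o2_per_glucose,
            "ko_o2": self.ko_o2,
            "kla0": self.kla0,
            "kla_reference_fill": self.kla_reference_fill,
            "inhibition_ic50": self.inhibition_ic50,
            "od_to_cdw": self.od_to_cdw,
            "gv_slope": self.gv_slope,
            "dt": self.dt,
            "t_end": self.t_end,
        }
        for name, value in positive.items():
            if value <= 0:
                raise DomainError(f"{name} must be > 0, got {value}")
        nonneg = {
            "mu_max": self.mu_max,
            "ks_glucose": self.ks_glucose,
            "lag_per_mM": self.lag_per_mM,
            "od0": self.od0,
            "noise_sd": self.noise_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise DomainError(f"{name} must be >= 0, got {value}")
        if not 0 <= self.yield_biomass < 1:
            raise DomainError(
                f"yield_biomass must be in [0, 1), got {self.yield_biomass}"
            )
        if not 0 < self.o2_efficiency <= 1:
            raise DomainError(
                f"o2_efficiency must be in (0, 1], got {self.o2_efficiency}"
            )


@dataclass(frozen=True)
class SimulatedVial:
    """Trajectories of one simulated vial (times in h, O2 in umol)."""

    times: np.ndarray
    od: np.ndarray
    gv: np.ndarray
    glucose: np.ndarray  # mM
    o2_headspace: np.ndarray  # umol
    o2_dissolved: np.ndarray  # umol
    solvent_c_medium: float  # mM, constant over the run
    o2_consumed: float  # umol, cumulative
    o2_supply_total: float  # umol sealed in at t=0


def simulate(
    params: SimulationParams,
    system: VialSystem | None = None,
    dose: float = 0.0,
    compound: Compound = STYRENE,
    medium: MediumSpec | None = None,
    prep_temperature: float = 20.0,
    rng: np.random.Generator | None = None,
) -> SimulatedVial:
    """Integrate one vial; ``dose`` is uL of neat solvent added at t=0.

    Raises :class:`StepSizeError` when ``mu_max * dt > 0.1`` (the explicit
    biomass update would be too coarse) and verifies the oxygen mass
    balance (consumed + remaining = sealed-in supply) to 1e-6 relative
    tolerance on every run.
    """
    if system is None:
        system = VialSystem()
    if medium is None:
        medium = MediumSpec()
    if params.mu_max * params.dt > 0.1:
        raise StepSizeError(
            f"mu_max * dt = {params.mu_max * params.dt:.3f} > 0.1; "
            "reduce dt for a stable integration"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)

    state = equilibrate(dose, system, compound)
    c_sty = state.c_medium  # mM, constant: the organism does not degrade it
    f_sty = 1.0 / (1.0 + c_sty / params.inhibition_ic50)
    yield_eff = params.yield_biomass * f_sty
    o2_per_glc_eff = (
        params.o2_per_glucose * (1.0 - yield_eff) * params.o2_efficiency
    )  # umol O2 per umol glucose
    lag = params.lag_per_mM * c_sty

    supply = oxygen_supply(system, medium, prep_temperature=prep_temperature)
    v_m = system.v_medium  # mL; umol / mL = mM below
    n_head0 = supply.n_o2_headspace
    c_sat0 = medium.o2_solubility / O2_MOLAR_MASS  # mg/L / (g/mol) = mmol/L
    kla = params.kla0 * params.kla_reference_fill / system.v_medium
    dt = params.dt

    # glucose (mM) consumed per unit OD increase
    glc_per_od = (
        params.od_to_cdw / (yield_eff * GLUCOSE_MOLAR_MASS) * 1e3
        if yield_eff > 0
        else np.inf
    )

    n_steps = int(np.ceil(params.t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    od = np.empty(n_steps + 1)
    glucose = np.empty(n_steps + 1)
    o2_head = np.empty(n_steps + 1)
    o2_diss = np.empty(n_steps + 1)

    x = params.od0
    s = medium.glucose_conc
    n_head = n_head0
    c_do = c_sat0 if n_head0 > 0 else supply.n_o2_dissolved / v_m
    consumed = 0.0
    od[0], glucose[0], o2_head[0], o2_diss[0] = x, s, n_head, c_do * v_m

    for i in range(1, n_steps + 1):
        t = times[i - 1]
        f_s = s / (params.ks_glucose + s) if s > 0 else 0.0
        f_o = c_do / (params.ko_o2 + c_do) if c_do > 0 else 0.0
        mu = params.mu_max * f_s * f_o * f_sty if t >= lag else 0.0

        dx = x * np.expm1(mu * dt)  # exponential biomass update
        ds = dx * glc_per_od if np.isfinite(glc_per_od) else 0.0
        if ds > s:  # cap at the glucose actually left
            scale = s / ds if ds > 0 else 0.0
            dx *= scale
            ds = s
        our = ds * o2_per_glc_eff / dt  # mM h^-1 in the liquid

        c_sat_eff = c_sat0 * (n_head / n_head0) if n_head0 > 0 else 0.0
        # semi-implicit dissolved-O2 update (stable for kla * dt >> 1)
        c_do_new = (c_do + dt * kla * c_sat_eff - dt * our) / (1.0 + dt * kla)
        if c_do_new < 0.0:
            # oxygen cannot go negative: scale this step's growth down to
            # what the pool plus transfer can actually cover
            our_max = (c_do + dt * kla * c_sat_eff) / dt  # rate at c_do_new = 0
            scale = our_max / our if our > 0 else 0.0
            dx *= scale
            ds *= scale
            our = our_max
            c_do_new = (c_do + dt * kla * c_sat_eff - dt * our) / (1.0 + dt * kla)
        transfer = kla * (c_sat_eff - c_do_new) * dt * v_m  # umol into liquid
        n_head -= transfer
        consumed += our * dt * v_m
        c_do = c_do_new
        x += dx
        s -= ds
        s = max(s, 0.0)

        od[i], glucose[i], o2_head[i], o2_diss[i] = x, s, n_head, c_do * v_m

    remaining = n_head + c_do * v_m
    total0 = supply.n_o2_total
    if abs(consumed + remaining - total0) > _BALANCE_RTOL * total0:
        raise AssertionError(
            f"oxygen balance violated: consumed {consumed:.6f} + remaining "
            f"{remaining:.6f} != supply {total0:.6f} umol"
        )

    gv_clean = (od - params.gv_intercept) / params.gv_slope
    noise = rng.normal(0.0, params.noise_sd, size=gv_clean.shape) if params.noise_sd else 0.0
    return SimulatedVial(
        times=times,
        od=od,
        gv=gv_clean + noise,
        glucose=glucose,
        o2_headspace=o2_head,
        o2_dissolved=o2_diss,
        solvent_c_medium=c_sty,
        o2_consumed=consumed,
        o2_supply_total=total0,
    )


@dataclass(frozen=True)
class WellSpec:
    """One well of a simulated plate.

    ``blank`` wells carry sterile medium (no inoculum, no growth) and are
    labelled with the :data:`~sightkit.growth_analysis.BLANK_CONDITION`
    condition so the analysis picks them up as optical background.
    ``overrides`` patches individual :class:`SimulationParams` fields for
    this well's condition.
    """

    well: str
    dose_ul: float = 0.0
    condition: str = ""
    blank: bool = False
    overrides: dict = field(default_factory=dict)


def simulate_plate(
    layout: list[WellSpec],
    params: SimulationParams | None = None,
    system: VialSystem | None = None,
    seed: int = 0,
    compound: Compound = STYRENE,
    medium: MediumSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every well of a 6x4 plate (wells A1..D6, at most 24).

    Returns ``(timeseries, layout_frame)`` in exactly the CSV dialect the
    growth-analysis readers consume: the time series indexed by ``time_h``
    with one column per well, the layout indexed by ``well``.  Replicate
    wells share the latent trajectory for identical parameters but draw
    independent noise from per-well child seeds, so the output is fully
    deterministic for a fixed ``seed``.
    """
    if params is None:
        params = SimulationParams()
    seen: set[str] = set()
    for spec in layout:
        if not _WELL_RE.match(spec.well):
            raise LayoutError(
                f"invalid well id {spec.well!r}: expected rows A-D, columns 1-6"
            )
        if spec.well in seen:
            raise LayoutError(f"duplicate well id {spec.well!r}")
        seen.add(spec.well)
    if len(layout) > _MAX_WELLS:
        raise LayoutError(f"at most {_MAX_WELLS} wells per plate, got {len(layout)}")

    times = None
    columns: dict[str, np.ndarray] = {}
    rows = []
    children = np.random.SeedSequence(seed).spawn(len(layout))
    for spec, child in zip(layout, children):
        p = replace(params, **spec.overrides) if spec.overrides else params
        if spec.blank:
            p = replace(p, od0=0.0)
        rng = np.random.default_rng(child)
        vial = simulate(p, system=system, dose=spec.dose_ul, compound=compound,
                        medium=medium, rng=rng)
        if times is None:
            times = vial.times
        columns[spec.well] = vial.gv
        rows.append(
            {
                "well": spec.well,
                "condition": BLANK_CONDITION if spec.blank else spec.condition,
                "dose_ul": spec.dose_ul,
                "solvent_mM": vial.solvent_c_medium,
            }
        )

    ts = pd.DataFrame(columns, index=pd.Index(times if times is not None else [],
                                              name="time_h"))
    layout_frame = pd.DataFrame(rows).set_index("well") if rows else pd.DataFrame(
        {"condition": [], "dose_ul": [], "solvent_mM": []},
        index=pd.Index([], name="well"),
    )
    return ts, layout_frame


def write_plate(
    ts: pd.DataFrame, layout_frame: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``gv.csv`` and ``plate.csv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gv_path = out / "gv.csv"
    layout_path = out / "plate.csv"
    ts.to_csv(gv_path)
    layout_frame.to_csv(layout_path)
    return gv_path, layout_path
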