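# sightkit

Closed-vial cultivation analytics for solvent-tolerance work.

Characterizing microbial growth in the presence of volatile solvents
(styrene, toluene, ...) requires hermetically sealed glass vials — and
sealing a culture changes everything: the solvent partitions between
medium and headspace, oxygen is a fixed one-time inventory, and growth is
observed only indirectly through an image-derived "Green Value" signal.
`sightkit` is the computational companion for such experiments. It is
aimed at microbial physiologists and strain engineers running
solvent-tolerance screens or adaptive laboratory evolution (ALE) in
sealed-vial platforms.

## What it computes

**Solvent partitioning and dosing.** At equilibrium a volatile solute
distributes between the aqueous phase and the headspace according to
c_air = k · c_m (k = 0.148 for styrene at 30 °C). For a sealed vial with
medium volume V_m and headspace V_a, the aqueous concentration of a dose
of n mol is

    c_m = n / (V_m (1 + k V_a / V_m)),

inverted to give the neat-solvent volume for a target concentration:

    V_solvent = V_m (1 + k V_a / V_m) · c_m · M / ρ.

Above the solubility limit (2.8 mM for styrene) the aqueous phase caps
and the excess forms a neat organic phase — the "second phase" used as
the maximum selection pressure in tolerance ALE.

**Oxygen/glucose budget.** A sealed vial's oxygen supply is
P V_a x_O2 / (R T) (ideal gas at sealing conditions) plus the dissolved
term; demand for complete glucose consumption with biomass yield Y_X/S is
n_glc (1 − Y_X/S) · 6. The budget report identifies the limiting
substrate.

**ALE ramp planning.** Stepwise concentration schedules (default: 1.0 mM
start, 0.25 mM increments) with automatic switch-over to second-phase
dosing at the solubility limit, each cycle carrying its dose volume.

**Green-Value growth analysis.** Linear GV↔OD₆₀₀ calibration, ΔGV
dynamic range, lag time (tangent method against sterile-blank wells),
maximum specific rate (sliding-window log-slope), stationary-entry time,
reliability flagging, and the HPLC glucose/gluconate co-elution
correction. Metrics are computed on raw GV; OD conversion is opt-in.

**Closed-vial simulator.** A seeded synthetic-data generator (Monod
growth under headspace-limited oxygen transfer and dose-dependent solvent
inhibition, observed through the GV transform with Gaussian noise) that
emits exactly the CSV dialect the analysis reads, so the entire pipeline
is testable without an instrument. See `docs/methods.md` for the model
and its limits.

## Worked example

How much styrene gives 1 mM in the aqueous phase of the default vial
(4.937 mL total, 600 µL medium)?

```sh
$ sightkit dose --target-mM 1.0
{"mode": "aqueous", "target_mM": 1.0, "dose_ul": 0.1427609110375276}
{"n_total": 1.2418760000000002, "c_medium": 1.0, "c_air": 0.148, "n_medium": 0.6,
 "n_air": 0.641876, "n_organic": 0.0, "organic_phase_present": false, "v_organic": 0.0}
```

0.143 µL of neat styrene yields 1.00 mM in the medium; note that of the
1.24 µmol dosed, more than half (0.64 µmol) sits in the headspace — the
reason open-vessel dosing under-delivers volatile solvents.

Is the default culture oxygen- or carbon-limited?

```sh
$ sightkit o2budget
{"n_o2_headspace": 37.85456357333356, "n_o2_dissolved": 0.17062500000000003,
 "n_o2_total": 38.02518857333356, "n_glucose": 12.0,
 "n_glucose_oxidizable": 6.337531428888926, "biomass_yield": 0.396,
 "n_o2_demand": 43.488, "limiting_factor": "oxygen"}
```

The sealed-in 38.0 µmol of O₂ could fully oxidize only 6.3 µmol of the
12.0 µmol glucose inventory; even crediting 39.6% of the glucose to
biomass, the demand (43.5 µmol) exceeds the supply — oxygen limits.

Plan the tolerance-ALE ramp:

```sh
$ sightkit schedule
cycle,mode,target_mM,fraction_v_v,dose_ul,inoculum_od
1,aqueous,1.0,,0.1427609110375276,0.05
2,aqueous,1.25,,0.17845113879690952,0.05
3,aqueous,1.5,,0.2141413665562914,0.05
...
8,aqueous,2.75,,0.39259250535320084,0.05
9,second_phase,,1.0,6.0,0.05
10,second_phase,,1.0,6.0,0.05
```

Eight aqueous cycles climb from 1.0 to 2.75 mM; cycle 9 switches to a 1%
v/v second phase (6 µL), holding the aqueous phase at saturation.

Generate a synthetic plate and analyze it:

```sh
$ sightkit simulate --seed 42 --out-dir fixtures
$ sightkit analyze --timeseries fixtures/gv.csv --layout fixtures/plate.csv
```

The analysis consumes the blank wells as optical background and reports
per-well ΔGV, lag (h), maximum rate (h⁻¹), stationary-entry time, and a
reliability flag.

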