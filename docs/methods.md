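# Methods

`sightkit` models the physics and bookkeeping of cultivating microbes in
hermetically sealed glass vials — the setting used for solvent-tolerance
work, where a volatile toxicant such as styrene must not evaporate during
the experiment. This note records the models, the parameter choices, and
the boundaries of what the synthetic-data tests can and cannot show.

## Closed-system solvent partitioning

A sealed vial contains medium (volume V_m) and headspace (V_a). At
equilibrium a volatile solute obeys c_air = k · c_medium with k the
dimensionless air/medium partition coefficient (0.148 for styrene at
30 °C). Mass balance over the two phases gives the aqueous concentration
of a dose of n mol:

    c_m = n / (V_m · (1 + k · V_a / V_m))

and the inverse — the neat-solvent volume for a target c_m —

    V_solvent = V_m · (1 + k · V_a / V_m) · c_m · M / ρ.

Above the aqueous solubility limit (2.8 mM for styrene) the model caps
c_m at the limit, sets the headspace to k times the limit, and routes the
excess to a neat organic phase. A dose landing exactly on the saturation
capacity is classified as saturated aqueous *without* an organic phase
(the tie-break matters for the ramp planner's mode switch).

Assumptions: the volume displaced by the dose itself is neglected
(sub-µL doses against multi-mL phases); k is applied without temperature
correction, with a warning when the system temperature is more than 2 °C
from the coefficient's reference temperature; kinetics of the approach to
equilibrium, septum losses, and multi-solvent mixtures are out of scope.
Internally all arithmetic uses mol, L, and g; µmol, mM, and µL exist only
at the interface, because the dosing formula as usually written mixes mL,
L and g·cm⁻³ and that is where unit bugs live.

Styrene's molar mass (104.15 g·mol⁻¹) and density (0.906 g·cm⁻³) are CRC
reference constants bundled with the registry; the partition coefficient
and solubility limit are literature values at 30 °C.

## Oxygen and glucose budgets

A sealed vial receives oxygen exactly once. The supply is the ideal-gas
headspace term P·V_a·x_O2/(R·T) — evaluated at *preparation* conditions
(20 °C, 101.3 kPa; vials are sealed on the bench, not in the incubator) —
plus the dissolved term, the medium's O₂ solubility (9.1 mg·L⁻¹ at 20 °C)
times the fill volume. The dissolved term is small (~0.17 µmol at 600 µL)
but included by default; a flag drops it. For the default geometry
(4.937 mL vial, 600 µL fill) the supply is 38.0 µmol.

Demand: complete oxidation consumes 6 mol O₂ per mol glucose, so the
38 µmol supply oxidizes 6.3 µmol glucose if no biomass forms, against a
12.0 µmol inventory (20 mM × 600 µL). With a biomass yield Y_X/S the
demand is modelled as

    n_O2 = n_glucose · (1 − Y_X/S) · 6,

reading the yield as the mass fraction of glucose routed to biomass and
fully oxidizing the remainder. This is a deliberate simplification — a
rigorous electron balance would use the biomass elemental composition —
but it is the natural back-of-envelope form, and with Y_X/S = 0.396 it
puts the default condition's demand at 43.5 µmol, above the 38.0 µmol
supply: oxygen, not carbon, limits the sealed culture. The classifier
reports `oxygen`/`carbon`, with a ±1% band reported as `balanced`; all
comparisons run at full precision and rounding is display-only.

## ALE ramp planning

The tolerance-evolution schedule raises the aqueous target from 1.0 mM in
0.25 mM increments each cultivation cycle. Whether a cycle exactly at the
solubility limit is run before switching to second-phase dosing is
genuinely open; the planner's default switches as soon as the next target
would *exceed* the limit (2.75 mM is the last aqueous cycle; cycle 9 is
the first 1% v/v second-phase cycle), and `include_saturation_cycle`
inserts an explicit 2.8 mM cycle first. A start above the limit yields an
all-second-phase schedule, flagged rather than rejected. Each cycle
carries its dose volume from the partitioning model and the transfer
inoculation density (OD₆₀₀ 0.05). When a culture is "ready" for transfer
is not scheduled here — that judgement belongs with the growth metrics.

## Green-Value analysis

The Growth Profiler's Green Value (GV) correlates linearly with OD₆₀₀
(fitted calibration of the form od = a·gv + b, e.g. a = 0.078,
b = −2.412 for the reference condition), but the relation shifts with
cell morphology and fails under solvent stress (emulsions, aggregates).
Headline metrics are therefore computed on raw GV; conversion to OD
equivalents is available but opt-in, and predictions below the
calibration's zero crossing are clamped to 0 and flagged.

Per-curve metrics:

* **ΔGreen Value** between two stated times (default 0 h and 10 h),
  linearly interpolated — the dynamic-range readout used to choose fill
  volumes.
* **Lag time.** With a sterile-blank GV available (blank wells are part
  of every sensible closed-vial layout), the background-subtracted signal
  is proportional to biomass *including the inoculum*, and the classic
  tangent construction — extrapolating the maximum-slope window of
  ln(GV − blank) back to the inoculum level — recovers the true lag
  exactly for exponential growth. Without a blank the estimator falls
  back to the first crossing of baseline + 5% of the dynamic range,
  which is robust to noise but includes part of the rise time (a
  rate-dependent positive offset).
* **Maximum specific rate.** Maximum ordinary-least-squares slope of
  ln(background-subtracted GV) over a sliding window (5 points), with
  windows admitted only where the growth signal exceeds 20% of the
  dynamic range so the log transform never runs in the noise floor
  (ε = 10⁻⁶ GV units additionally stabilizes it). With a blank this is
  unbiased for exponential growth; with only baseline subtraction the
  earliest windows are biased high because the inoculum signal has been
  subtracted out — which is precisely why the blank path exists.
* **t_stationary**: first crossing of baseline + 95% of the
  baseline-subtracted range (defined on the subtracted range so the
  metric is invariant under affine GV rescaling).
* **reliable** is False when the dynamic range does not clear three
  baseline standard deviations; stationary-phase GV in solvent cultures
  is additionally suspect (aggregates inflate it) and should be read
  qualitatively.

The 5% lag threshold, 95% stationary fraction, 20% rate-window floor and
the 3σ noise floor are analysis conventions, not measured constants; all
are configurable.

HPLC co-elution: glucose and gluconate co-elute on the ion-exclusion
method used for supernatant analysis, but only gluconate absorbs at
210 nm, so glucose = max(mixed RID signal − gluconate DAD signal, 0),
clamping (with a warning) the negative differences that noise can
produce.

## The closed-vial simulator

The simulator exists so every analysis component can be exercised
end-to-end without an instrument. It is phenomenological and unfitted:
its obligations are the qualitative closed-vial behaviours — complete
glucose consumption without solvent stress, residual glucose under a
second styrene phase, less residual glucose at lower fill volumes,
dose-dependent lag and rate depression — not any measured trajectory.

State: latent OD X, glucose S (mM), dissolved O₂ (mM), headspace O₂
(µmol). Growth follows

    µ = µ_max · S/(K_S+S) · DO/(K_O+DO) · 1/(1 + c_sty/IC50),

suppressed until t exceeds `lag_per_mM · c_sty`. The dissolved styrene
concentration c_sty is the partitioning model's equilibrium value, held
constant (the organism does not degrade the solvent). Glucose is drawn at
(dX/dt)/Y_eff with an effective yield Y_eff = Y·f_solvent — stressed
cells divert carbon from biomass to maintenance respiration. Oxygen
uptake is 6·(1 − Y_eff)·η per mole of glucose, with η = 0.85 a
respiratory-efficiency factor standing in for the flexible Pseudomonas
electron-transport chain: it lets the unstressed default condition finish
its 12 µmol of glucose within the ~38 µmol sealed-in oxygen even though
the naive stoichiometric demand (43.5 µmol) exceeds the supply — the same
apparent contradiction the budget module quantifies. The dissolved pool
is replenished from the headspace at kLa scaled inversely with fill
depth (kLa₀ = 100 h⁻¹ at the 600 µL reference fill, a plausible value
for a shaken sub-mL culture), with the saturation level proportional to
the remaining headspace oxygen.

Defaults: µ_max = 0.6 h⁻¹ and Y_X/S = 0.396 (a glucose-grown
Pseudomonas), K_S = 0.05 mM, K_O = 0.003 mM (growth is insensitive to DO
until it nearly vanishes), IC50 = 1 mM styrene on the growth rate,
1.5 h of lag per mM dissolved styrene, inoculum OD 0.05, 0.4 g CDW·L⁻¹
per OD unit, 30 h horizon at dt = 0.05 h. With these choices a 1% v/v
second phase leaves ~6 mM of 20 mM glucose unconsumed at 600 µL fill and
progressively less at lower fills — the right ordering and magnitude,
chosen once, not tuned to any measured residual.

Numerics: biomass uses an exponential update (exact for constant µ over
a step); the stiff dissolved-O₂ balance is integrated semi-implicitly so
kLa·dt ≫ 1 stays stable; a step is scaled down if it would drive glucose
or dissolved O₂ negative; `µ_max · dt > 0.1` raises a step-size error.
Every run asserts the oxygen closure consumed + remaining = supply to
10⁻⁶ relative tolerance. Halving dt moves the final OD by far less than
0.5% because the endpoint is fixed by mass balance, not by the
integrator.

Observation model: GV = (OD − b)/a (the inverse calibration line) plus
additive Gaussian noise on GV only; OD is never observed. Plate
simulation derives independent per-well noise streams from spawned child
seeds, so replicates share the latent curve and the whole plate is
reproducible bit-for-bit from one seed. Blank (sterile) wells are plain
members of the layout and feed the analysis's background estimate.

What the simulator does **not** emulate: aggregate- and
emulsion-distorted stationary-phase optics, morphology-dependent GV/OD
drift, CO₂ accumulation and pH, solvent loss through septa, and any
evolutionary dynamics. Passing parameter-recovery tests therefore shows
the estimators are correct *for clean monotone curves observed through a
linear transform* — not that they are robust to every artifact of real
stationary-phase solvent cultures, which the `reliable` flag and the
documented stationary-phase caveat address instead.

## Test problem sizes

The parameter-recovery sweep runs a 3×3×3 grid over µ_max
(0.4–0.8 h⁻¹), lag coefficient (1–3 h·mM⁻¹) and styrene dose
(0.10–0.20 µL), on noiseless curves sampled every 0.25 h, asserting lag
recovery within one sampling interval and rate recovery within 5% of the
generating exponential-phase rate µ_max/(1 + c/IC50). Partition
properties use 200 round-trip and 1000 conservation draws over random
geometries. These sizes give stable verdicts in seconds; nothing in the
conclusions changes at larger sizes.

## Known limitations

* The yield-corrected oxygen demand is a mass-fraction reconstruction,
  not an electron balance; treat its absolute value as a budgeting
  heuristic.
* k_air/medium is temperature-fixed; runs far from the reference
  temperature only warn.
* Lag estimates without a sterile blank carry a rate-dependent positive
  offset by construction.
* The simulator's η, IC50, lag coefficient and kLa are order-of-magnitude
  choices; the simulator supports testing and teaching, not prediction.
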