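# Methods

## Scope

`heatstrain` couples three components: (i) a multi-node human bioheat
model (17 segments, 85 nodes including a central blood compartment) with
an error-signal-driven active system; (ii) a serial-model estimator of
clothing insulation from thermal-manikin records; and (iii) a heat-strain
evaluation layer (safety thresholds, acceptable maximum working time,
work/rest schedule comparison).  A synthetic-data module generates every
input the pipeline needs, so all stages are testable offline.

## Passive system

The body is split into head, neck, chest, back, pelvis and left/right
shoulder (upper arm), arm (forearm), hand, thigh, leg (calf) and foot.
Head and pelvis have six tissue layers (skin, fat, muscle, core, artery,
vein); neck, chest and back have four (skin, core, artery, vein); the
twelve limb segments have five (skin, core, artery, vein, superficial
vein): 84 tissue nodes plus a central blood pool.

Each tissue node obeys

    c dT/dt = Q + B + D − (C + R + E − SW) − RES,

with heat production Q, blood exchange B, conduction D, and, at skin
nodes, convective/radiative/evaporative exchange with the environment and
shortwave gain.  Respiratory loss RES is applied at the chest core only.
Blood exchange follows the classic multi-node convention: every tissue
node is coupled to the central pool through its perfusion
(1.067 W/K per L/h); the central-blood equation is the negative sum of
all couplings, so blood transport conserves energy identically.
Conduction conductances are symmetric per layer pair, so conduction also
conserves energy identically; the per-step energy check in the test suite
verifies that total storage equals production minus losses to within
1e-6 of the flux magnitude.

Segment areas, layer masses, specific heats, basal perfusion and basal
heat production are an editable packaged table
(`data/body_composition.csv`).  Masses scale linearly with body weight,
areas with the DuBois surface area, basal production with the basal
metabolic rate (revised Harris-Benedict), so one table serves any body
size.  Layer mass splits and organ perfusion rates are set from standard
physiological magnitudes (brain ≈ 35 L/h, trunk viscera dominating basal
production, basal skin flow ≈ 15 L/h for a 60-kg body); artery/vein nodes
get high specific flows to emulate their flow-through character.

**Activity semantics.**  Schedule activity levels are physical activity
ratios — multiples of the person's basal metabolic rate.  For the default
worker (1.70 m, 60 kg, 20 y) one unit is ≈ 78 W, so wire-hooking work at
3.3 produces ≈ 257 W.  This is the convention of the model family this
package re-implements; note it differs from the 58.2 W/m² "met" of
comfort standards by the ratio of basal rate to seated rest.  Work (and
shivering) heat is distributed over muscle-bearing nodes by the
`work_frac` column and adds muscle perfusion at 0.86 L/h per W.

## Active system

Setpoints are not shipped constants: they are defined as the passive
steady state of the same body, nude, at operative 30 °C, 50 % RH, still
air and basal metabolism (solved by relaxation plus a Newton polish, and
cached).  By construction all error signals vanish exactly where the
unregulated body is in balance, which makes thermoneutral homeostasis a
structural property rather than a tuned one.  For the default worker this
puts the head-core setpoint near 36.9 °C and mean skin near 34.2 °C.

Effectors are memoryless functions of the error signals
Err = T − Tset:

* integrated skin signals: area-weighted positive (warm) and negative
  (cold) skin errors;
* sweating: `csw`·Err(head core) + `ssw`·(warm − cold), clamped at zero,
  distributed by segment area with local modulation 2^(Err_skin/10) and a
  whole-body secretion cap (20 g/min);
* vasodilation/constriction: `cdl`/`sdl` and `cst`/`sst` analogues; skin
  flow per segment is (basal + dilation share)/(1 + constriction share),
  clipped to [0.3, 130] L/h per m² of segment area;
* shivering: `csh`·(cold skin integral)·(cold head-core error), capped.

Gains live in `data/coefficients.csv`.  The shipped values were
calibrated so that the package reproduces the published whole-body
responses of the 17-segment model family under the built-in scenarios
(neutral homeostasis, hot-environment plateaus, schedule recovery); they
are of the same order as the classic multi-node control coefficients
(sweating 220 W/K on the core error vs. the classic 371 W/K; dilation
75 L/h/K).  The skin-signal dilation gain (33 L/h/K) is deliberately
stronger than the classic value so that a resting, hyperthermic body
keeps its skin perfused and continues to dump heat by evaporation during
rest breaks in the heat.

## Environmental exchange

Dry loss per segment is a series resistance: intrinsic clothing
insulation 0.155·I_cl plus the surface air layer 1/(f_cl·(hc+hr)); the
loss splits into C and R in proportion hc:hr, with the operative
temperature as the driving potential.  hr is linearised about the mean
radiant temperature with emissivity 0.95 and effective radiating fraction
0.73.  hc is the maximum of a natural-convection floor (3.2 W/m²K), a
forced power law 8.6·v^0.61, and an activity term
4.6·(M/A/58.2 − 0.85)^0.39 that represents the air movement generated by
the working body's own motion (the same mechanism as the classic
metabolic-rate-dependent convection of the two-node comfort model, with
the coefficient calibrated within that family's range).  The activity
term vanishes below ≈ 0.85 met so the setpoint derivation and resting
conditions stay on the still-air floor.

Evaporation converts the dry resistances to vapour resistances through
the Lewis relation (16.5 K/kPa) and the permeability index i_cl (0.34 for
the cotton ensemble):  Emax = area·(Psat(Tsk) − Pa)/Re, clamped at zero
when the gradient reverses (condensation is not modelled).  Realised
evaporation is min(0.94·E_sweat + 0.06·Emax, Emax): a skin without sweat
still loses the minimum diffusion fraction.  Saturation pressure uses the
Tetens (Magnus) formula, accurate to ~0.1 % over 0–50 °C.  Respiration is
the standard 0.0014·M·(34 − Ta) + 0.0173·M·(5.867 − Pa).  Shortwave gain
is absorptance (0.7) × projected-area fraction (0.3) × area × irradiance,
attenuated by 0.6 under clothing; all built-in scenarios use zero
irradiance and MRT = Ta, because the scenarios are defined by air
temperature and humidity only.

**Sweat accounting.**  The reported cumulative "sweat loss" is the
evaporated water mass (1 g = 1 mL), including the insensible diffusion
component; sweat secreted beyond the evaporative ceiling drips and is
tracked separately (`secreted_ml`).  In humid heat the two differ by a
factor of ~3: the evaporated mass is the quantity that matches reported
whole-body water-loss magnitudes for this model family, and it is the
physiologically meaningful mass actually leaving the body surface as
vapour.  The 5 %-of-body-mass sweat threshold is applied to the same
series.

## Clothing ensemble

The default ensemble is a summer work uniform whose whole-body basic
insulation (0.709 clo, clothing area factor 1.36) matches a
thermal-manikin measurement of such an ensemble; the per-segment split is
not observable from whole-body values, so a torso-heavy editable table is
shipped: bare head and hands, double-covered hips carrying the largest
local insulation, boots on the feet, per-segment f_cl = 1 + 0.31·clo.

## Insulation estimator

`SerialInsulationModel` consumes long-format manikin records (segment,
condition nude/clothed, run, minute, surface temperature, heat loss,
area).  The last `window` minutes per run are averaged and runs are
averaged; local resistance is (Tsi − Ta)·ai/Hci; whole-body values are
area-factor-weighted sums with f_i from the nude areas.  Basic insulation
uses the serial-model correction I_cl = I_t − I_a/f_cl (the variant
(I_t − I_a)/f_cl is available behind `printed_form=True` for comparison
but is inconsistent with standard whole-body results).  Segments present
in only one condition are dropped with the area factors renormalised and
the event logged — mirroring protocols in which the head is not measured.
Standard errors propagate the minute-to-minute spread of the heat-flux
signal through the delta method.

## Heat-strain evaluation

AMWT is the first minute at which core temperature reaches 39 °C or
cumulative sweat loss reaches 5 % of body mass, censored at 300 min.
Core temperature is read at the head core node (hypothalamic proxy;
pelvis core selectable).  `amwt_grid` runs one simulation per (Ta, RH,
wind) cell — defaults Ta 30–42 °C × RH 40–90 % × {0.2, 1, 2} m/s — and
emits a long-format table plus a chart-ready matrix.  Effective working
time counts only work-block minutes before the first core crossing.
Schedule comparison reports end-of-horizon sweat per schedule, percent
reduction against the continuous-work baseline, and a least-squares slope
of sweat against total rest minutes across the rest-containing schedules.

The built-in scenario set fixes the study conditions: trajectories at
33 °C/45 %, 35 °C/50 %, 37 °C/55 % (still air, 180 min); schedules
C1–C4 (continuous, 60/30, 60/45, 60/60 work/rest) at 38 °C/55 % over
240 min.  Rest blocks stay in the same environment at 1.05× basal —
light seated recovery with no cooler refuge.  The rest level is the one
genuinely unconstrained scenario parameter; 1.05 was chosen because the
relative ordering and spacing of the four schedules' safe working times
is sensitive to it, and this value makes the 60/45 strategy (C3) complete
its scheduled work without crossing 39 °C while the 60/30 strategy (C2)
fails during its second work block, the qualitative pattern the
evaluation layer is designed to expose.

## Numerics

Integration is explicit first-order with a 60-s reporting step,
sub-divided internally to at most 5 s so the smallest nodes (hand/foot
arteries, superficial veins, time constants ≈ 20 s) stay well inside the
Euler stability limit; control laws and surface fluxes are re-evaluated
every sub-step.  Halving the reporting step changes a 180-min core
trajectory by less than 0.02 °C (self-convergence test).  A non-finite
temperature aborts the run naming the offending node.  All simulations
start from the setpoint state.  The plateau-detection default declares
thermal equilibrium when the minute-sampled core rate stays below
0.003 °C/min for 15 consecutive minutes; the "plateau value" is the mean
of the last 30 min.  Degenerate inputs are validated at construction
(non-positive dimensions, humidity outside [0, 100], negative insulation,
rest levels below basal, zero-duration blocks all raise).

## Synthetic data

The manikin generator inverts the serial-model arithmetic
(H = ΔT·a/R_true, optional multiplicative Gaussian noise, two 30-min runs
at one-minute cadence, 34 °C surface in a 24 °C chamber), so the
noiseless round trip through the estimator recovers the ground truth
exactly — the module's primary oracle — and noisy recovery tightens as
1/√window.  It emulates steady records only: no warm-up drift, chamber
fluctuation or inter-segment leakage, so passing tests demonstrate the
estimator's arithmetic and averaging, not robustness to a misbehaving
chamber.  Random environments/schedules are uniform draws within the
validated ranges, reproducible by seed.

## Limitations

* Physiological coefficients are calibrated at the whole-body level;
  per-segment temperatures are plausible but not individually validated.
* No acclimatisation, circadian drift, hysteresis, age/sex effector
  differences (beyond basal-rate scaling), Q10 metabolism, or
  brown-adipose dynamics.
* Clothing is static: no pumping, wind penetration, or moisture
  accumulation in fabric; condensation on skin is ignored.
* The activity-convection term is a whole-body scalar; posture and
  angle-resolved solar geometry are out of scope.
* AMWT charts inherit the model's deterministic character: no
  inter-individual variability is propagated.
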