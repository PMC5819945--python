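# Methods

`hiberphys` implements the computational chain used in pre-hibernation and
hibernation studies of small heterotherms (juvenile dormice are the guiding
case): classification of nest-temperature traces into activity and torpor,
two-segment trajectory models for weekly growth/fattening/torpor series,
open-flow respirometry, gross-energy-intake accounting, and doubly-labelled
water (DLW) body composition and energy expenditure. Every stage is
exercised against a synthetic-data generator with programmed ground truth;
this note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Activity classification from nest temperature

The input is a nest-temperature trace T_nest sampled at 1-min intervals and
an ambient trace T_a at 30-min intervals, linearly interpolated onto the
nest grid (extrapolation is refused). The classifier works on the
difference D = T_nest − T_a:

1. D is smoothed with a **centered moving average over `ma_window` = 100
   samples** (symmetric truncation at the edges). A centered window is used
   because a trailing window would add a ~50-min phase lag to every onset
   estimate.
2. The **mean of the smoothed series is the threshold**: smoothed D at or
   above the mean means the animal is resting in the nest, below the mean
   means it is active outside. Ties go to in-nest (deterministic,
   conservative toward rest). The threshold is computed per analysed
   record, matching weekly logger downloads.
3. A **refinement pass with `refine_delta` = 0.5 °C** catches short nest
   returns at night and short nest exits by day, which move D only briefly.

The refinement is a forward state machine over the threshold labels,
working on a lightly smoothed D (`refine_ma_window` = 15 samples) compared
against trailing-window extrema (`ref_window` = 120 samples):

* **in-nest → outside** when D falls more than 0.5 °C below its recent
  maximum, or crosses the global threshold downward — but only if the
  decline is *faster* than `torpor_entry_rate_max` = 0.15 °C/min. A
  vacated nest cools toward ambient within minutes (time constant ~10 min),
  whereas a nest cooled by a torpid occupant relaxes over hours; slow
  declines therefore stay in-nest for bout detection, even where deep
  torpor drags the smoothed difference below the global threshold.
* **outside → in-nest** when D crosses the threshold upward, or rises more
  than 0.5 °C above its recent minimum *at a warming rate above the same
  limit* — only an occupied nest rewarms quickly; an empty nest merely
  drifts with ambient.

Two details deviate from the simplest reading of the standard recipe and
are deliberate. First, the ±0.5 °C comparisons use trailing-window extrema
rather than the level at the start of each run: the run-entry level is
contaminated by smoothing lag, and slow ambient drift would otherwise
accumulate into false triggers that latch the state for the rest of the
night. Second, the exit/return decisions are gated by the cooling/warming
rate; this encodes the same kinetic contrast that separates nest exits from
torpor entries, and is what keeps torpor bottoms labelled in-nest. A naive
per-sample transcription of these rules lives in the test suite and the
production classifier must agree with it exactly.

Degenerate input (a constant difference series) yields an all-in-nest
labelling with a warning, not an error.

## Torpor-bout detection

Bouts are detected inside in-nest episodes on the lightly smoothed D (the
ambient correction removes the daily ambient swing, which is larger than
the torpor dip itself). Within an episode, the euthermic baseline is the
0.9 quantile of D. A candidate bout is a maximal run of samples more than
`torpor_depth_delta` = 2 °C below baseline. For each candidate:

* the **entry rate** is measured from the last sample at or above the
  *local pre-bout level* minus `onset_anchor_delta` = 1 °C down to the
  depth crossing; candidates with entry rate above 0.15 °C/min are
  discarded as nest exits (fast cooling), the rest are torpor entries;
* the **onset** is the anchor crossing extrapolated backward along the
  entry tangent by `onset_anchor_delta / rate` — on a first-order cooling
  transient this lands at the start of the decline;
* the bout **closes** when D recovers to within 2 °C of baseline; the
  reported **offset** is the start of the terminal rewarming, obtained by
  extrapolating the rewarming tangent from the recovery crossing back to
  the bout-bottom level;
* bouts whose full excursion (onset to recovery crossing) is shorter than
  `torpor_min_duration` = 60 min are discarded. The screen intentionally
  uses the excursion, not the reported duration, so a genuine bout exactly
  at the limit is not lost to boundary-estimation error.

The local pre-bout level (0.75 quantile over up to `backwalk_limit` = 240
samples before the descent) is used for onset anchoring because the
episode-wide baseline is biased upward by thermal-lag asymmetry over the
day. On generator scenarios with default noise, bout counts are exact and
onset/offset errors stay within ±15 min for bout durations from 60 to
420 min.

Weekly summaries assign each bout to the 7-day block (counted from
experiment start) containing its onset, with its full duration. Weeks
without nest data (respirometry weeks) can be filled from respirometry
torpor flags: presence is recorded with frequency 1 and missing durations,
absence with zeros; activity time is missing either way.

## Hibernation metrics from body temperature

For implanted-logger winter traces (0.5 °C resolution), a sample is torpid
iff T_b is below `euthermy_threshold_body` = 30 °C. The threshold is a
package default — the torpid/euthermic boundary for body temperature is not
standardized — and is reported in the output metadata. Maximal torpid runs
are bouts; hibernation starts at the onset of the first bout of at least
`hibernation_bout_threshold` = 24 h (closed boundary: a 24.0-h bout counts)
and ends at the offset of the last such bout. Arousals are the euthermic
intervals strictly between consecutive hibernation bouts; the terminal
rewarming defines the end of hibernation and is not counted. Mean
inter-bout-euthermy duration averages the euthermic time in those gaps;
minimal T_b is taken over torpid samples within the hibernation span. A
trace with no qualifying bout returns a "no hibernation detected" result,
distinct from an error.

## Two-segment trajectories

Weekly series (body mass, body length, torpor parameters, activity time)
are modelled as two joined linear segments:

* `rise_then_plateau`: y = a + b·t for t ≤ τ, then constant at the plateau
  a + b·τ (continuity imposed; the slope/plateau description implies it);
* `flat_then_change`: y = c for t ≤ τ, then c + b·(t − τ).

The breakpoint τ (time of plateau, or starting time of torpor/activity
change) is estimated by profiling: an exhaustive grid of candidates
(observation times plus midpoints, at least two observations at or left of
each candidate, the last observation included so the single straight line
is nested in the search), ordinary least squares for the linear parameters
at each candidate, and the RSS minimizer wins; ties go to the earliest
candidate. The grid search replaces visual breakpoint identification; on
noise-free two-phase data it recovers the generating parameters exactly
(RSS = 0). Slope standard errors are conditional on the selected τ —
breakpoint uncertainty is not propagated, a documented limitation.
Recovery at late-born mass-gain settings (slope 9.4 g/week, breakpoint
week 5, residual SD 2 g, 9 weekly observations) gives a mean slope bias
under 5% and the breakpoint within ±0.5 week in over 90% of replicates.

Triplicate body-length QC: if two of three readings agree (within 0.05 cm
reading precision) and the third differs from them by at least 0.5 cm, the
third is excluded and the pair averaged; otherwise all three are averaged.

Group contrasts on fitted parameters are reported as group means,
differences, and 95% percentile bootstrap confidence intervals over
animals. Mixed-effects modelling is out of scope; single-animal groups are
flagged with undefined intervals.

## Respirometry and energy intake

Open-flow oxygen consumption uses

    VO2 = FD · (FiO2 − FeO2) / (1 − FiO2 · (1 − RQ)),

with FD the dry flow in l/h at STPD, converted to ml O2/h. RQ defaults to
0.85 for animals fed ad libitum and 0.70 for intermittently fasted animals
(fat oxidation). Flows measured at ambient conditions are converted with
flow × 273.15/(273.15+T) × (P − P_water)/101.325; this standard ideal-gas
correction is the package's choice of STPD formula. ADMR, MR-day and
MR-night are equal-time-weight means over the retained window after
excluding a configurable 24-h habituation period, with day/night windows
taken from the configured photoperiod.

Gross energy intake multiplies the mass of food eaten by the caloric
content of its proximate composition (protein 23.3, fat 39.6, fibre/NFE
17.5 kJ/g; water contributes nothing). Perishable food (apple) is first
corrected for water loss by comparing provisioned and leftover masses on a
dry-matter basis; the apple composition ships as the USDA fresh-mass
values and is configurable. Cumulative intake Ecum (MJ) and its weekly
mean are computed over the study period; missing weeks are flagged and
excluded, never zero-filled.

## Doubly labelled water

Total body water comes from the plateau method: the dilution space
N = dose × (dose enrichment − background)/(plateau enrichment −
background), with the equilibration sample drawn ~1 h post-dose. The 18O
space is divided by its space factor 1.007 to give TBW (the 2H factor is
1.041); fat-free mass is TBW/0.732 via the hydration coefficient, and fat
mass is body mass minus FFM, flagged if negative.

For the multi-point protocol, elimination constants k_o and k_d are the
least-squares slopes of log excess enrichment against time over all
post-dose samples (with two samples this is the two-point closed form),
and dilution spaces come from the fitted excess at the equilibration time
— elimination is anchored at equilibration, which makes the noiseless
round trip exact. CO2 production uses the two-pool equation with fixed
dilution-space ratio (Speakman's formulation):

    rCO2 [mol/day] = (N_o/2.078)·(k_o − k_d) − 0.0062·k_d·N_o,

with N_o in mol. TEE converts rCO2 through the Weir factors at the
configured RQ (16.318/RQ + 4.602 kJ per litre CO2), and water turnover is
rH2O = k_d·N_d in g/day. k_o ≤ k_d implies non-positive CO2 production and
flags the budget as physiologically invalid. The exact published DLW
variant differs between laboratories; the equation used is recorded in
every output.

Error propagation note: because rCO2 is proportional to the *difference*
k_o − k_d (here 0.10/day against k's of 0.45 and 0.35), a 1% enrichment
noise level that leaves each k within a fraction of a percent still moves
individual TEE estimates by several percent; TEE recovery is therefore
assessed on replicate means.

## The synthetic-data generator

The generator emulates all six input streams with known truth; its
defaults are the study conditions the package is validated under.

* **Ambient**: daily sinusoid (mean 22.5 °C, amplitude 4.5 °C, warmest at
  15:00) plus AR(1) noise (φ = 0.95, innovation SD 0.15 °C) on the 30-min
  grid — the simplest process matching a mid-20s mean with ~3 °C SD and a
  15–30 °C seasonal range.
* **Nest trace**: first-order relaxation toward a state-dependent target —
  ambient + 6 °C elevation when occupied and euthermic, ambient when the
  animal is outside (time constant 10 min), euthermic level minus the
  programmed depth during torpor (time constant 90 min), rewarming with a
  15-min constant — plus 0.2 °C Gaussian measurement noise (below logger
  resolution). The 10 vs 90 min contrast is a plausibility choice: nest
  cooling kinetics are not reported, only the qualitative fast/slow
  contrast, and the constants keep the two events separable. All are
  configurable.
* **Winter body trace**: multiday bouts near a 5.3 °C cold-room ambient
  separated by brief euthermic arousals (entry/arousal constants 60/15
  min), quantized to 0.5 °C.
* **Growth**: rise-then-plateau lines for mass and length with Gaussian
  noise; defaults follow a late-born cohort (mass 38.8 g + 9.4 g/week to
  week 5, SD 2 g).
* **Respirometry**: programmed day/night VO2 profile (90 ml O2/h day,
  2:1 night:day) inverted through the VO2 equation to excurrent O2
  fractions, with an elevated first habituation day.
* **DLW**: two-isotope exponential washout from a 29.28-g pool (body mass
  55 g, k_o 0.45/day, k_d 0.35/day, 5 g/kg dose) with 1% multiplicative
  enrichment noise; weekly food masses sized so mean gross energy intake
  is ~1.0 MJ/week.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: logger drift and battery failure gaps,
nest-material heterogeneity and occupancy by more than one animal,
half-entries and shallow test bouts, photoperiod-driven changes in
activity timing across the season, isotope fractionation effects, and
behavioural variation between animals. Validation here shows the
algorithms recover what the models encode; parameters for field data
should be audited against a manually scored subset.

## Numerical choices and degenerate inputs

All times are minutes from experiment start; weeks are consecutive 7-day
blocks. The moving average uses window i − ⌊w/2⌋ … i + ⌈w/2⌉ − 1 with
truncation at the edges. Threshold ties label in-nest. A constant response
series fits slope 0 at the first grid candidate with a warning. Gapped
weeks are flagged and excluded from denominators rather than imputed.
Seeded runs are byte-identical end to end: the pipeline manifest carries a
SHA-256 checksum per output, and rerunning a config reproduces every file
exactly.
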