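# Methods

This note documents the statistical model behind `wormspan`, the
conventions it fixes where the field leaves room, the synthetic-cohort
generator, and the limits of what the test suite can establish.

## Data model and day conventions

The unit record is one worm on one scoring day. Day 0 is the L4
moult; worms are scored daily as alive/dead, with censoring for the
classical FUdR-era causes (bagging, wall-crawling, extrusion of
internal organs) plus `other`. The recorded death day is the first
day the worm was scored dead, so a worm alive on days 0..d−1 and dead
on day *d* has lifespan *d*. Unknown censoring-cause strings are
errors, never silently coerced. Motility is staged A/B/C while alive
and must be scored on every alive day (a permissive flag relaxes
this); within a worm the stage sequence may never improve — the
staging is defined by progressive loss of function, and a recorded
reversal is treated as a scoring error. Files are UTF-8 delimited
text, one row per worm-day (tab or comma, auto-detected), which
preserves the daily stage trajectory that a per-worm wide format
would lose.

## Survival estimation

Kaplan-Meier estimation and the Mantel-Cox log-rank test are
delegated to `lifelines`; Benjamini-Hochberg correction to
`statsmodels`. Conventions fixed here:

* **Mean lifespan** is the arithmetic mean of observed death days with
  censored worms excluded. This is the estimator under which
  published percent-effect columns recompute exactly from published
  means; the KM restricted mean (RMST) is always reported alongside,
  and the two agree exactly when there is no censoring.
* **Uncertainty**: reported as SEM = SD/√(number of deaths). Summary
  tables at cohort sizes of hundreds of worms conventionally print
  ±0.2–0.5 d, which is a standard error, not a per-worm SD; both are
  emitted.
* **Maximum lifespan** has no standard definition; the default is the
  mean of the top decile of death days (robust to a single straggler),
  with the absolute maximum and the 90th percentile selectable.
* **Ties**: all deaths scored on the same day share one event time;
  censorings tied with deaths leave the risk set after the deaths.
* p-values below 2.0E-16 are reported as "<2.0E-16" in formatted
  tables (the floor of double-precision tail probabilities); the
  numeric value is kept internally.

## Healthspan decomposition

Two transition analyses convert daily stage scores into survival
problems: exit from {A} (loss of full mobility) and exit from {A, B}
(onset of frailty). Death while still inside the stage set **ends the
sojourn and counts as an event** (a composite endpoint). This
convention is forced by arithmetic: only with death-as-event do the
three differences of restricted means

    mobile = RMST_exit{A}
    impaired = RMST_exit{A,B} − RMST_exit{A}
    frail = RMST_death − RMST_exit{A,B}

sum identically to the mean lifespan, which published decompositions
(e.g. 17.3 + 1.5 + 1.8 = 20.6 d) satisfy. All three terms use KM
restricted means (area under the curve to the last observation) so
censored worms contribute risk time; with `censor_policy="exclude"`
censored worms are dropped instead, matching the convention of daily
bar-chart tallies, which exclude dead and censored animals. Stage
fractions are stored at the 0.1 % report precision and days at 0.1 d;
strain-vs-control fraction changes are computed on these
report-precision fractions, which is the arithmetic under which
published comparison values (−4.8 %, −19.5 %) reproduce exactly.

The ordering RMST_exit{A} ≤ RMST_exit{A,B} ≤ RMST_death holds
structurally on censoring-free data and to KM-estimation error
otherwise; a violation would indicate inconsistent scoring.

## Synergy classification

Effects are percent changes of the **mean** endpoint vs the shared
control (classification on medians is out of scope). The categories
follow the SynergyAge-style definitions over the subset lattice; the
decision procedure is:

1. if every proper subset is measured and the target's effect exceeds
   Δ(S₁) + Δ(S₂) for every bipartition by more than `tol_rel` of that
   sum → **full synergism**;
2. if the singletons are measured and the target exceeds their sum by
   more than the tolerance → **simple synergism**;
3. if neither rule's coverage is available but one incremental chain
   of measured strains increases at every extension → **partially
   known synergism** (the definition's scope is exactly the case
   where only a chain was built);
4. otherwise, with singletons available: **additive** when
   |Δ − ΣΔ| ≤ tol·ΣΔ, **intermediate** between the best singleton and
   the sum, **antagonistic** at or below the best singleton (but
   beneficial), **deleterious** at or below zero.

Two deliberate choices. First, synergism must clear the *same*
relative tolerance that defines the additive band (default 10 %,
configurable, recorded in every output): with strict ">" alone, any
sampling fluctuation just above exact additivity would be promoted to
full synergism, and a classifier that calls half of all exactly
additive experiments synergistic is not useful. The 10 % default is
a convention, chosen because a combined effect ~9 % short of the
singleton sum is conventionally described as "almost additive"; it is
not estimated from data. Second, classification is point-estimate
based; significance feeds only the network edge coloring. The
evidence list carries every margin and threshold so users can apply
their own uncertainty reasoning.

Note that full synergism does **not** logically imply the simple-
synergism condition for N ≥ 3 (a bipartition sum can be smaller than
the singleton sum); the evidence reports both margins.

Strain networks are directed graphs whose edges add exactly one
intervention; nodes carry the mean endpoint value (the vertical
coordinate in the conventional drawing) and a shape class by
intervention count; edges carry the percent change and a color class
(increase/decrease, or neutral when below a percent threshold or not
significant after BH adjustment). Backgrounds are never mixed: a
*daf-16* panel forms its own lattice. Export is lossless GraphML or
node-link JSON via `networkx`.

## Endpoint statistics

Group summaries use SD with ddof = 1 and SEM = SD/√n. One-way ANOVA
is `scipy.stats.f_oneway` with an explicit error on degenerate (zero
total variance) input. Dunnett's many-to-one comparisons use
`scipy.stats.dunnett`, which integrates the equal-correlation
multivariate-t null of the maximum statistic with a seeded generator —
reproducible from the seed, no critical-value tables. Comparisons are
two-sided by default. Stress-assay survival fractions are analyzed
with the replicate plate as the unit of observation.

## The synthetic-cohort generator

The generator exists so that every downstream analysis has a
ground-truth oracle; its defaults emulate the design of a
combinatorial lifespan experiment at 20 °C.

* **Mortality**: Gompertz hazard h(t) = a·e^{bt} with per-strain
  multiplier exp(Σβ + Σγ) on the hazard. Defaults a = 7·10⁻⁵/d,
  b = 0.40/d give a recorded wild-type mean lifespan of 20.7 d with
  SD ≈ 3.2 d (SEM ≈ 0.2 d at n ≈ 255, the pooled three-replicate
  size). Default β for the panel genes (−2.16 odr-3, −1.48 ife-2,
  −0.36 cku-70) reproduce the published single-intervention mean
  lifespans (26.1, 24.4, 21.6 d analytic); interactions default to 0
  because lifespan effects in the panel were additive.
* **Motility**: a progressive three-stage process with its own
  Gompertz hazards for A→B and B→C (defaults sized so a wild-type
  worm spends roughly 85–90 % of life mobile and ~1–2 d in each of
  the impaired and frail stages), per-gene log-hazard effects on the
  transitions, and a frailty multiplier (default 2) on the death
  hazard while impaired or frail. The multiplier is a free simulator
  parameter: no quantitative coupling between motility stage and
  residual mortality has been published, so it is not an estimate.
* **Observation process**: continuous event times are rounded **up**
  to the next scoring day (a worm dying during day 3–4 is found dead
  at the day-4 check); per-day Bernoulli censoring (default 0.005/d)
  with a 40/40/20 bagging/wall/extrusion cause mix; survivors at the
  horizon (default 80 d) are censored with cause `other`. Cohort
  sizes default to 85 worms × 3 replicates.
* **RNAi dilution**: 1:1 mixes of an RNAi clone with empty-vector
  bacteria are modeled as a configurable attenuation of β (default
  0.5 of the full-knockdown effect).
* **Randomness**: one named substream per strain, derived from the
  master seed and a CRC-32 of the strain label, so adding a strain
  never perturbs the draws of the others; identical config + seed is
  byte-identical output.
* **Pumping**: counts/min decline exponentially from 250/min at day 1
  (rate 0.15/d, reaching ~30/min by day 15); interventions slow the
  decline multiplicatively; Gaussian noise (SD 25), truncation at
  zero, rounding; 14 worms filmed at days 1, 5, 10, 15. Stress
  assays are binomial survivor counts.

What the generator does *not* emulate: operator-to-operator scoring
variability, plate effects and shared-environment correlation within
replicates, non-Gompertz late-life mortality plateaus, motility-stage
reversals, and any mechanistic link between the endpoints (pumping is
simulated independently of mortality). Tests passing on simulated
cohorts therefore establish the correctness and calibration of the
estimators under the stated model, not the biological fidelity of the
model itself.

## Numerical choices and problem sizes

Gompertz sampling uses exact inversion of the cumulative hazard
(piecewise, with the frailty multiplier applied from the A-exit time
onward), so no discretization error enters beyond the intended
daily rounding. The analytic oracle for the recorded mean is
E[⌈T⌉] = Σ_{d≥0} S(d), which the test suite checks against Monte
Carlo and against simulated cohorts (within 2 SEM at n = 400–500).
Null-calibration checks use 500 simulated two-arm experiments of 60
worms each (log-rank type-I error) and 500 four-group Dunnett
families of 15 values each; parameter recovery uses 500 worms per
strain. These sizes put Monte-Carlo noise comfortably inside the
0.05 ± 0.02 calibration band and keep the whole suite under a minute
of simulation time; they are choices of the package, recorded in
`scripts/acceptance.py`.

## Known limitations

* The transition analyses assume the stage sequence is monotone; data
  with genuine B→A recoveries cannot be represented.
* The additive/synergistic boundary is a point-estimate rule with a
  conventional tolerance; it performs no hypothesis test of
  interaction, and lattices built from noisy means at small n will
  classify unstably near the boundary (the evidence margins make this
  visible).
* Mean-lifespan summaries exclude censored worms; under heavy,
  non-independent censoring the RMST column is the safer quantity,
  and the two are reported side by side so disagreement is visible.
* Dunnett p-values are quasi-Monte-Carlo approximations (seeded);
  repeated runs with different seeds vary in the fourth decimal.
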