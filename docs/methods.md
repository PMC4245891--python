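# Methods

## Setting and assumptions

Self-reported 24-hour dietary recalls systematically understate energy
intake. Both corrections in this package rest on two assumptions:

1. **Energy homeostasis.** Body weight is stable over the survey window,
   so true intake EI equals total expenditure EE. Percent misreporting is
   therefore identified as pct = 100·(EE − EI_claimed)/EE, and corrected
   intake as EI = EI_claimed/(1 − pct/100). Populations on weight-loss
   diets violate this; the standard exclusions (special diet, atypical
   day, non-reporters, minors) remove the worst offenders.
2. **Transportability.** Misreporting behaviour (regression method) or
   the activity distribution (intake-shift method) observed in a training
   study with measured expenditure — doubly labeled water in the OPEN
   cohort, adults 40–69 — carries over to the survey population being
   corrected.

RMR is predicted, not measured, with the adult Schofield weight-only
equations (kcal/day), age bands [18, 30), [30, 60], (60, ∞); ages above
the top band reuse the >60 coefficients. The weight+height variant is
also implemented and selectable (`equation="weight_height"`). Because RMR
is predicted, the permissive lower plausibility bound IndEI ≥ 1 is the
default; the stricter Goldberg-style cut-off of 1.35 is available via
`goldberg_bounds()` but deliberately not the default, since measured PAL
values below 1.35 (down to ~1.16) are documented in calorimetry studies.
Upper bounds are 2.8 (women) and 3.5 (men) — extremely active but short
of expedition-level expenditure; values exactly on a bound count as
plausible.

## Regression correction

OLS of percent misreporting on sex code (1 = male, 2 = female), age
(years), weight (kg), log EI_claimed and IndEI_claimed = EI_claimed/RMR.
The published training-study coefficient vector is shipped as a constant
(`default_open_model()`): intercept 298.19, sex −2.30, age −0.36, weight
0.21, log EI −35.84, IndEI −30.47, R² 0.84. Refitting
(`MisreportRegression(...).fit()`) uses statsmodels OLS; backward
stepwise selection removes, one at a time, the covariate with the largest
two-sided coefficient p-value above α (default 0.05), ties broken toward
the later-listed candidate, intercept never removed. A normal QQ
diagnostic for the outcome is provided (`normality_diagnostic`), since
the linear model presumes approximately normal misreporting.

**Calibration of the published constants.** Two things about the
published table are underdetermined or inconsistent:

* the base of the log-intake term is not stated;
* the printed intercept fails the least-squares identity. Any OLS fit
  satisfies *mean prediction = mean outcome* on its own training sample,
  but with the printed slopes and the published training-summary moments
  (mean intake 2346 kcal, mean expenditure 2627 kcal, hence mean
  misreporting ≈ 10.7%), the natural-log reading predicts a mean of
  roughly −26% and the base-10 reading roughly +130%, under either
  Schofield variant.

`calibrate(reference)` therefore (a) scores the four
log-convention × RMR-variant combinations by the gap between their
population-mean prediction on a reference table and the observed mean
misreporting (natural log wins by a wide margin, and is the default
convention), and (b) restores the least-squares identity by recentring
the intercept so the model is mean-unbiased on the reference
(`source="recalibrated"`; the slopes are never touched). The chosen
convention and RMR variant are recorded inside the model object so
corrections are reproducible. Without the recentring, the constant model
as printed pushes borderline reporters *below* the lower bound and cannot
reproduce the published order-of-magnitude improvement; with it, the
simulated failure rate falls below 2%, matching the published behaviour.

Predicted percentages are clamped to [−99, 99] before inversion so
covariate extremes met during resampling cannot drive the denominator of
EI/(1 − pct/100) to zero. The inversion itself is exact (round-trip error
< 1e−10 kcal) inside the clamp.

By default models are fitted on, and applied to, non-Black subsets
(`include_black=False`), mirroring the training study's finding that
misreporting patterns differed for Black participants with too few
observations to model separately; a flag lifts the restriction.

## Intake-shift correction

Per sex: fit a log-normal to measured PAL by maximum likelihood (moments
of ln PAL); published fits are geometric mean/SD 1.83/1.14 (men) and
1.63/1.13 (women). The published "mean (SD)" pairs are read as
*geometric* moments: an arithmetic PAL SD of 1.14 would place a large
share of the population below the biological floor PAL = 1, whereas a
geometric SD of 1.14 (≈13% dispersion) matches doubly-labeled-water
summaries. The fitted curve is interpolated to the simulated population
size with deterministic plotting-position quantiles
exp(μ + σ·z((i−0.5)/n)) — a quantile correspondence rather than random
draws, so the method needs no seed of its own and the two choices
converge as n grows. After a stable sort of IndEI_claimed (ties keep
input order), rank i's gap (PAL-quantile − IndEI) is converted to
calories with that person's own RMR, and the per-person gaps are averaged
into one shift per sex, added to every reported intake of that sex and
floored at 0 kcal. The shift is stratified by sex only: one-way ANOVA of
PAL across weight-status groups (`compare_pal_by_group`) showed no
difference in the training data, consistent with the wider literature.

## Monte-Carlo survey simulation

The survey table is cleaned (`apply_exclusions`, reporting per-rule
counts), optionally filtered (all adults / non-Black / non-Black 40–69),
and partitioned into sex × 10-year age bins (18–29 … 70+; half-open
bins, interior edges belong to the upper bin). Each replicate draws each
individual's cell from a census-style weight table, then one complete
record (height, weight, reported intake jointly — preserving their
correlation) uniformly with replacement from the stratum, plus an age
uniform within the bin. Whole-record resampling is the default; the
bundled synthetic weight table is uniform over age bins with a 0.49/0.51
male/female split, and real census weights can be supplied to emulate a
specific survey year. Per-replicate RNG streams derive from
(master seed, replicate index), so runs are bitwise reproducible and any
single replicate can be regenerated alone. Failure is evaluated on raw
IndEI_claimed for the baseline and on corrected intake/RMR for either
method; the regression path additionally pools per-person intake deltas
across replicates for quartile reporting, and the shift path records the
per-sex shift of every replicate.

## Synthetic data: what it emulates, and what it does not

`generate_open_like` emulates the training cohort: ages uniform on
[40, 69], 45.7% women, weight truncated-normal 81.0 (17.6) kg (> 35 kg),
reported intake log-normal with mean 2346 and SD 808 kcal, and mean
misreporting ≈ 10.7%, so the implied mean expenditure (~2630 kcal)
matches the published summary. Misreporting is generated as the linear
model plus Gaussian noise (default SD 5 percentage points, chosen to
keep the refit R² in the region of the published 0.84 while leaving a
non-trivial residual).

The generative direction matters. Because two covariates (log EI and
IndEI) are functions of the generated intake, generating "expenditure
first, then solve intake from the model" is a per-person fixed point;
with the steep published slopes that fixed point is unstable or
multi-rooted for a sizeable share of realistic activity levels, and noise
inside it is amplified several-fold and becomes correlated with the
covariates, making OLS inconsistent. The generator therefore draws the
*claimed* quantities first, computes pct = linear model + noise, and
derives EE = EI/(1 − pct/100) — attributing the noise to the expenditure
measurement, which is realistic for doubly labeled water. Consequences:
recovery of the generating coefficients is exact at zero noise and
unbiased under noise (verified over independent seeds), the generator's
true coefficient vector is attached as `df.attrs["true_model"]` (slopes
are the published values; the intercept is recentred on the sample, for
the mean-consistency reason above), and PAL = EE/RMR is a *derived*
quantity, guarded to (1.05, 4.5) — a generator-level safeguard, not a
method assumption. The induced PAL distribution is tighter than the
published per-sex fits, so tests that need a specific PAL law draw it
directly instead.

`generate_nhanes_like` emulates a survey flavor by its published
summary moments — 1971-like: weight 69.2 (15.3) kg, intake 1876 (884)
kcal, ages 18–74; 2007-like: weight 80.0 (20.7) kg, intake 2120 (1050)
kcal, ages 18–79 — with intake log-normal, split by sex with a
female/male reported-intake ratio of 0.70 (overall mean preserved;
chosen once as typical of sex differences in reported intake). With
`implausible_fraction_target` set, a common shift of the per-sex log-mean
is solved (Brent's method on the exact normal-probability expression,
taking the under-reporting branch) so the expected out-of-bounds fraction
matches the target. Not emulated: survey design weights, clustering and
non-response; real census age–sex margins; within-stratum correlation
between intake and body size (intake is drawn independently of weight);
day-to-day intake variance. Passing tests therefore demonstrate the
methods' internal correctness and directional behaviour on populations
with the published moments — not their exact failure rates on the real
survey files, which also depend on the true joint distributions. In
particular, the synthetic intake dispersion leaves the intake-shift
method a higher residual failure rate (~20%) than is achievable on real
survey data, where reported-intake spread within sex is narrower.

## Numerical choices and problem sizes

* OLS and p-values: statsmodels; rank deficiency is detected before
  fitting and reported with the names of the dependent columns.
* Truncated normals, normal quantiles, ANOVA, QQ: scipy.stats.
* The acceptance script uses a 5,000-person training cohort and 100
  replicates of 10,000 individuals per method — sizes at which every
  Monte-Carlo quantity reported is stable to well under its tolerance —
  and derives all sub-seeds from the single `--seed`.
* Ties in stepwise elimination: remove the later-listed covariate.
* Negative adjusted intakes are floored at 0 kcal.
* Sex is coded 1 = male / 2 = female throughout so published
  coefficients apply verbatim; readers map M/F/male/female on input.

## Known limitations

* Both corrections are population-level: they recover plausible
  *distributions*, not any individual's true intake on a given day.
* The homeostasis identity transfers all model error into the corrected
  intake; populations undergoing weight change are out of scope.
* The published coefficient table could not be used exactly as printed
  (see calibration above); the recentring is principled but means the
  shipped constant model is faithful to the printed *slopes*, with an
  intercept anchored to the training summary moments rather than the
  printed 298.19.
* Race-specific models beyond the non-Black default, children and
  adolescents, pregnancy adjustments, and measurement-error deattenuation
  methods are out of scope.
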