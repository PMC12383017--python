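# Methods

This note documents the models, estimators, numerical policies and design
choices behind `dynapool`, and what validation on synthetic data does and
does not establish.

## Allometry

`W = a L^b` is estimated by ordinary least squares of `ln W` on `ln L`.
Log-scale estimation is the field standard when `r²` and a slope test are
reported, and it makes the lognormal-error assumption explicit: weight
residuals are multiplicative.  The isometry statistic

    t = (SD(ln L)/SD(ln W)) · |b − 3| · sqrt((n − 2)/(1 − r²))

is algebraically the Wald statistic `|b − 3| / SE(b)` of that regression
(a unit test asserts the identity).  Both standard deviations are taken on
the log scale, where the regression lives; taking them on the raw scale
would make the formula dimensionally incoherent.  Critical values come from
the t distribution at `df = n − 2` rather than printed lookup tables.  With
a numerically perfect fit (`r² = 1`) the statistic is undefined; the
implementation then concludes from `b` alone (tolerance `1e-9`).

The sex comparison is a slope-homogeneity F test on the `ln L × sex`
interaction, followed (only when slopes are homogeneous) by a common-slope
elevation test.  "ANCOVA on the length–weight relationship" is ambiguous;
this two-step reading is the standard one.  Unknown-sex fish are excluded.

## Growth

The von Bertalanffy function is fitted by nonlinear least squares on
individual (age, length) pairs with `scipy.optimize.least_squares`
(trust-region reflective, `ftol = 1e-9`, positivity bounds on `L∞` and
`k`).  Initialisation is deterministic: `L∞₀ = max(L)/0.95`, `k₀` from a
Ford–Walford-style regression of mean length at age `t+1` on mean length at
age `t` (clipped to [0.01, 1], falling back to 0.2 when fewer than three
consecutive age-class pairs exist), `t0₀ = 0`.  Same data ⇒ bit-identical
estimates.  Confidence intervals use the Gauss–Newton covariance
`s²(JᵀJ)⁻¹` with the t quantile at `n − 3` df; simulation shows ≥90%
empirical coverage at nominal 95% for survey-scale data (300 fish, 15 mm
additive noise).

Ages are integer annulus counts; no birth-date fractional adjustment is
applied (none is defensible without a birthdate convention).  Age 0 ("0+")
is legal and treated as `t = 0`.

Derived ages are closed forms: `t_i = ln(b)/k + t0` zeroes the weight
acceleration; `t_c = [k t0 − ln M + ln(bk + M)]/k` zeroes the derivative of
unfished cohort biomass `e^{−M(t−t0)} W_t`.  Both are cross-checked in the
tests against dense-grid argmax oracles.  `φ = log10 k + 2 log10 L∞` uses
base-10 logarithms, the only reading consistent with values near 4.5 for
`L∞` in mm.  The weight curve clamps `(1 − e^{−k(t−t0)})` at zero below
`t0`, where a non-integer power of a negative base is otherwise undefined.

## Point estimates from interval estimates

When a source publishes only confidence intervals, the package uses the
interval midpoint as the point estimate (`IntervalEstimate.value`).  For
the shipped reference stocks this convention reproduces the published
derived ages and the quoted `L∞` range exactly, which is strong evidence it
is the convention those values were computed under.

## Mortality

`Z = k(L∞ − L̄)/(L̄ − Lc)` uses the arithmetic mean length of fish at or
above `Lc` (≥10 fish required).  The estimator is exact under continuous
exponential age structure and knife-edge selection.  **On integer-age data
it carries a discretisation bias**: with the selection length exactly at an
age-class mean length the large-sample limit is `k(e^Z − 1)/(1 − e^{−k})`
rather than `Z` (over 50% high at `Z = 0.8`), shrinking to under 10% when
`Lc` falls mid-way between age-class mean lengths.  The synthetic-data
consistency test therefore benchmarks the estimator against its analytic
plug-in limit under the discrete design (`bh_plugin_limit`), which is the
quantity it actually converges to, and a separate test checks recovery
within 15% of true `Z` in a realistic design (gear recruiting fish from
age 2, i.e. `Lc = 100` mm under the default growth parameters).  Real
surveys, with continuous spawning dates and length noise, sit between the
two regimes.

Pauly's formula is evaluated by default as his original base-10 regression
with `L∞` in cm (`log10 M = −0.0066 − 0.279 log10 L∞ + 0.6543 log10 k +
0.4634 log10 T`); the coefficient set is often transcribed with natural
logarithms and mm, so that literal variant (`ln_mm`) is also provided.
Both variants place `M/k` inside the plausible 1.5–2.5 band for the
reference stocks.  Habitat temperature `T` and the selection length `Lc`
are survey metadata, not estimable from samples; both are explicit config
inputs, with helpers to back-solve `T` from a target `M`
(`implied_temperature`) and `Lc` from a published `Z` (`invert_lc`).  Every
such reconstruction is logged in the output record under `assumptions`.

`F = Z − M` and `E = F/Z` are exact identities, enforced by the result
type.  Negative `F` (M overestimated) is reported with a flag, never
clamped.  Diagnostic thresholds (`e^{−k} < 1`, `1.5 ≤ M/k ≤ 2.5`,
`Z/k > 3`) use strict inequalities at the boundaries.

## Yield per recruit

The relative dynamic-pool model assumes knife-edge selection at `Lc`,
cubic weight-at-length (`b = 3`) inside the yield integral, recruitment at
`t0`, and the closure `Z = M/(1 − E)` tying mortality to the exploitation
rate — the standard relative formulation, which the source model leaves
implicit.  The closed form is validated against an independent numerical
integration of the underlying age-structured catch equation (relative
error < 1e-4 over a random parameter sweep); this dual route is the
module's core correctness property.

`E_max` is found by bounded 1-D minimisation (`xatol = 1e-5`, verified
against a 1e-4-step grid argmax) after a unimodality pre-scan; `E_50`
by Brent root-finding on the normalised `B′/R − 0.5`.  `B′/R = (Y′/R)/F`
diverges as `E → 0`, so the reported ratio is normalised by its analytic
`E → 0⁺` limit (unfished biomass per recruit), making "biomass at 50% of
unfished" well defined; the raw `B′/R` is also reported.

The isopleth grid evaluates `Y′/R` over `(E, c)` at 0.01 steps and
reports two argmax readings: per-`E` (the best capture size at a given
effort) and global (the joint effort-and-size optimum).  For this model
the global optimum sits on the high-`E` edge at `c = 3/(M/k + 3) ≈ 0.59`
for `M/k ≈ 2.1` — the "maximum at `Lc/L∞ = 0.6`" of classic isopleth
analyses.  The per-`E` argmax at current exploitation rates is lower
(0.47–0.54 for the reference stocks); both are exposed because management
advice built on the 0.6 reading implicitly assumes the joint optimum.
The size-limit recommendation averages three metrics — length at `t_i`,
length at `t_c`, and the global-optimum catch length — reporting each
component alongside the mean.

## Synthetic populations

The generator draws integer ages with probability ∝ `e^{−Z t}` on
`0..max_age`, lengths as VBGF means times `(1 + N(0, cv))` (redrawn if
non-positive), weights as `a L^b` times lognormal noise, sex as Bernoulli,
then applies knife-edge selection at `Lc_gear`, drawing until the target
catch size is reached.  Defaults mirror a slow-growing high-plateau
stock: `L∞ = 591.23` mm, `k = 0.098`/yr, `t0 = −0.225`, `a = 2e-5`,
`b = 2.94`, `Z = 0.46`, `max_age = 13`, ~100 fish per survey.  Noise
levels (`length_cv = 0.08`, `weight_sd_log = 0.12`) are set to give
log–log `r² ≈ 0.98–0.99`, typical of river-fish length–weight data; the
reference source prints no `r²` to calibrate against.

What the generator does **not** emulate: recruitment variability,
seasonal growth oscillation, size-selective ogives (selection is a step
function), ageing error in annulus counts, and continuous birth dates.
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions, not robustness to their violation — with one
deliberate exception: the integer-age design violates the continuous-age
assumption of the `Z` estimator, and the tests quantify exactly that gap
(see Mortality above).

`recovery_experiment` runs a chosen stage over replicate simulations
(seeds `base + r`), recording estimates, CI coverage and failures as data
rows rather than exceptions.

## Problem sizes used in validation

Chosen to make Monte-Carlo error small relative to the tolerances while
keeping the full suite fast: 100 replicates for CI-coverage checks
(coverage ≥ 90% at nominal 95%), 500 replicates for type-I-error checks
(tolerance ±2 Monte-Carlo SE around α = 0.05), catches of 50 000 for
distributional checks on the generator, and 500/5 000/50 000 for the
consistency ladder.  The whole suite runs in well under a minute.

## Known limitations

* Single Pauly variant for `M` (no Hoenig/Then estimators); `M` is the
  dominant uncertainty in the derived chain and `T` is an assumption.
* No length-converted catch curves or Chapman–Robson `Z` alternatives.
* The relative `Y′/R` form hard-codes `b = 3`; mild allometry
  (`b ≈ 2.94`) introduces a small, conventional approximation.
* Replay mode inherits the printed rounding of its inputs; derived values
  can differ from unrounded-source computations in the last digit (the
  exploitation-rate identity at 3 d.p. is a documented example).
* No absolute yield per recruit, no F-based reference points (F₀.₁, F_MSY),
  no plotting (grids export as long-format CSV for any contour tool).
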