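# Methods notes

## Setting and model form

Two logistic screening equations estimate the probability of elevated serum
cholesterol (LDL-C or non-HDL-C ≥ 160 mg/dL) in adults aged 20–40 from
gender (male = 1), metabolic age (a bioimpedance body-composition summary in
years) and, for non-HDL-C, diastolic blood pressure. The package treats the
coefficient sets as *data* (JSON/YAML), with the published updated equations
shipped as defaults; any user-supplied logistic model over the same
predictor vocabulary runs through every stage unchanged. Where the device
measurement is unavailable, metabolic age is proxied by a fixed linear
combination of chronological age, BMI and gender; the proxy is intentionally
not clamped, so extreme inputs can produce implausible (even negative)
values that should be read as an out-of-range signal.

## Synthetic cohorts

Only marginal summaries of the study population are public, so the generator
draws independent truncated-normal marginals whose means/SDs equal the
validation-cohort values (n = 1099; 22.7% male; age 30.4 ± 4.7 y; BMI
22.9 ± 4.5 kg/m²; metabolic age 31.0 ± 12.6 y; DBP 70.4 ± 10.1 mmHg; SBP
115.5 ± 13.2 mmHg), with occupation assigned uniformly over the ten ISCO-08
major groups in the absence of a published distribution. Two numerical
choices matter:

* **Truncation** (age ∈ [20, 40], BMI > 12, metabolic age > 0, DBP > 35,
  SBP > 50 — the first three chosen to match eligibility and physiology,
  the last two as loose plausibility floors) is implemented by
  rejection-resampling, never hard clipping, to avoid probability atoms at
  the bounds. Because truncation alone would shrink realised moments (the
  age clamp cuts ~10% of the SD), the *parent* normal parameters are solved
  by moment matching so the truncated draws reproduce the specified
  mean/SD.
* **Joint structure** is a modelling choice, not an observed quantity: the
  default is independence, with an optional Gaussian-copula correlation
  matrix over the five continuous predictors for realism experiments. With
  heavy per-margin truncation the realised correlation is attenuated
  relative to the latent copula value; tests pin this behaviour down.

Randomness uses one root seed per cohort; per-stage child generators are
spawned from `numpy.random.SeedSequence` in a fixed order, so adding lipid
draws does not perturb the predictor draws.

Endpoints are simulated as `y ~ Bernoulli(expit(a + b·LP))` with the linear
predictor LP from a designated true model and configurable drift `(a, b)`.
`(0, 1)` gives a perfectly calibrated cohort; `b < 1` plants the
too-extreme-predictions pattern seen in overfit models. Note that `a` acts
at LP = 0, not at the LP mean: with `b ≠ 1` the *fitted* CITL differs from
`a` by approximately `(b − 1)·mean(LP)`. When the overfitting-style pattern
(curve above the diagonal at low risk, below at high risk, overall rate
roughly preserved) is wanted, set `a = (1 − b)·mean(LP)`. Continuous lipid
values can be drawn for descriptive cosmetics, but endpoints never come from
thresholding them — the validation machinery assumes the LP→outcome
structure. In `eq3_plus_noise` mode metabolic age is the linear proxy plus
Gaussian noise; the default noise SD of 4.44 y was derived analytically so
the observed-on-imputed R² is ≈ 0.87 under the default marginals
(var(proxy) ≈ 131.9 y² ⇒ noise² = 131.9·(1/0.87 − 1)).

What the generator does *not* emulate: real predictor correlations beyond a
user-supplied copula, measurement error in BIA output, longitudinal visits,
seasonal recruitment effects, and any genuine biological LP→lipid link.
Passing parameter-recovery tests therefore demonstrates correctness of the
estimators under the assumed data-generating process, not transportability
of the clinical models themselves.

## Performance metrics

AuROC is the Mann–Whitney concordance (ties ½) with the DeLong
structural-components variance; the CI method is a documented assumption
(the original analysis does not state one) and Wald intervals are clipped to
[0, 1]. CITL is the MLE intercept of a binomial GLM with LP as offset;
C-slope the joint-MLE slope of `logit = a + b·LP`; both with Wald CIs. The
E:O ratio uses the log-normal interval with SE(ln E:O) = √((1−φ)/(nφ)).
Discrimination labels follow the Hosmer–Lemeshow wording (≤0.5 none,
(0.5, 0.7] poor, (0.7, 0.8] acceptable, (0.8, 0.9] excellent, >0.9
outstanding).

Degenerate inputs raise typed errors rather than returning silently wrong
numbers: single-class outcomes, constant LP, and (quasi-)complete separation
(detected by zero residual deviance or diverging coefficients — a
quasi-separated dataset has no finite slope MLE). Probabilities are clipped
to [1e−12, 1−1e−12] before any logit. Calibration curves use equal-count
quantile bins (default 10) with exact binomial intervals, or a lowess
smoother (default span 0.75, another documented assumption); a constant risk
vector collapses to its single effective point.

## Recalibration and refitting

The default update is the joint MLE of `(α, β)` in `logit = α + β·LP`,
folded back into the equation as coefficients·β and intercept α + β·b₀. On
the data used for updating this forces C-slope = 1 and CITL = 0 exactly (to
solver tolerance), and re-updating is a fixed point — both are tested at
1e−6. A `sequential` variant takes α from the slope-fixed-at-one offset fit
and β from the joint fit; it does not exactly zero out same-data
miscalibration, which matches how some published post-update slopes sit
slightly off one, and is provided for sensitivity analysis. Refitting is a
full ML fit of the stated terms (guarded by n > 10·terms and zero-variance
checks) and, being nested above recalibration above the original model,
must weakly increase the log-likelihood — asserted in tests.

## Decision curves

Positivity is `p ≥ t` (ties positive; the convention is fixed and
documented because the source is silent). Net benefit, treat-all and the
per-100 net reduction in investigations follow the standard formulas; the
default grid is 0.01–0.60 by 0.01, covering the practically discussed
10–50% threshold range with margin; curves are unsmoothed. The "per 100"
scale (participants, not tests) is the implemented reading of the
investigation-reduction axis.

## Minimum sample size

Three precision criteria; the required n is their maximum.

* **C-statistic**: Newcombe-type variance
  `C(1−C)[1+(n/2−1)(1−C)/(2−C)+(n/2−1)C/(1+C)]/(n²φ(1−φ))`; the smallest n
  with 95% CI width ≤ target is found by doubling + integer bisection and is
  tight (n passes, n−1 fails).
* **Calibration slope**: the 2×2 Fisher information of the recalibration
  model under LP ~ N(μ, σ²) at the anticipated slope, integrated with fixed
  200-node Gauss–Hermite quadrature (relative error far below 1e−6 for
  these inputs). This deterministic integration replaces the
  large-simulated-sample approach of common implementations, whose printed
  results therefore differ from ours by Monte-Carlo noise of ~0.2–0.3%.
* **O/E ratio**: SE(ln O/E) = √((1−φ)/(nφ)). The target width is read on
  the ratio scale via the asymmetric exponential interval, solving
  `2·sinh(z·SE) = width` (default); a symmetric log-scale convention
  (`SE = width/(2z)`) is available. The criterion is sensitive at the ±5
  participant level to prevalence rounding, so specs can carry an exact
  event fraction (`oe_prevalence`) separate from the rounded headline
  prevalence; the shipped reproduction specs do.

## Case-mix benchmarking and fairness

The case-mix reference resamples participants (pairs, not residuals) with
replacement and simulates outcomes from the model's own predictions, so it
is exactly invariant to relabelling the observed outcomes; replicate means
and 2.5/97.5 percentiles summarise the distribution. Single-class or
separated replicates are skipped and counted, with a 10% cap before the run
aborts. The after-update benchmark can seed the simulation from either the
original or the updated model's predictions (`casemix_lp`), since summary
tables of this design are ambiguous about which is used.

Fairness tables compute subgroup AuROC by conditioning (independent
within-group ROC areas) and subgroup calibration by per-group recalibration
fits, which coincide with the saturated-interaction binomial GLM (verified
numerically in tests). Continuous covariates default to tertiles, with cut
points recorded in the group labels; subgroups under 20 participants or 5
events are flagged rather than dropped, and derived covariates
(waist-to-height ratio, fat/muscle percentage) are computed only when the
underlying fields exist, otherwise the covariate is reported unavailable.

## Pipeline

`run_validation` executes cohort synthesis/loading → eligibility → scoring →
validation → recalibration → DCA → sample size → benchmarking → fairness,
with stage-labelled errors and a manifest (SHA-256 per artifact, config
hash, seed). Figures are drawn only from tables that are themselves emitted
as CSV. Descriptive cohort comparisons use t (or opt-in rank-sum) tests for
continuous columns and Fisher's exact test for binary ones (chi-squared
beyond 2×2, e.g. the ten ISCO groups); the choice of test per column is
declared in configuration, not inferred from normality testing.

## Problem sizes used in the checks

Parameter-recovery tests run at n = 20,000 (slope/CITL drift recovery,
subgroup drift localisation) or n = 50,000 (refit coefficient recovery);
case-mix centring uses B = 1000 bootstrap replicates of an n = 1099 cohort;
property-based oracles (pairwise concordance, double-loop decision curves)
run exhaustively at n ≤ 50–100. These sizes give sampling error comfortably
inside the asserted tolerances while keeping the full suite fast.

## Known limitations

* The pre-update development-cohort coefficients are not shipped (they are
  user input); all drift regimes are expressed relative to the updated
  equations.
* DeLong CIs and the lowess span are assumptions where the original
  analysis is silent; both are swappable.
* Exact-integer agreement of all six published minimum sample sizes is not
  attainable under any single documented convention: four reproduce exactly
  (990, 624, 1566 with the exact event fraction, and the slope values to
  <0.3%); the non-HDL-C O/E minimum differs by 5 under every
  rounding/width-convention combination tried, consistent with an
  unpublished rounding choice in the original calculation.
* No shrinkage/penalised updating, no cost-effectiveness modelling, no
  Hosmer–Lemeshow test or Brier score (not part of the workflow replicated
  here).
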