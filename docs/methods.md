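# Methods

## The statistical question

The body mass index, weight/height², is a special case of the Benn-type
relative-weight index weight/height^p. The "right" exponent p is an
empirical property of a population: a good relative-weight index should be
uncorrelated with height (so that tall and short people are not
systematically mislabelled) while remaining strongly correlated with body
fatness. `bennscale` implements the grid-search derivation of such
sex-specific exponents and the downstream evaluation of the resulting
formulas as screening and risk-prediction tools.

Two selection criteria are implemented, both operating on age-adjusted
partial Pearson correlation curves r(p) computed at every point of a
uniform exponent grid (default −50.00 to 50.00 in steps of 0.01):

* **height independency** — choose p where the correlation between
  weight/height^p and height is zero;
* **fatness dependency** — choose p where the correlation with a fatness
  measure (body-fat percentage, fat mass, fat-free mass, weight, waist
  circumference, waist:hip ratio, waist:height ratio) is maximal.

The partial correlation of x and y given age is the Pearson correlation of
the residuals of x and y after least-squares regression on [1, age].
Confidence intervals use the Fisher z transform,
tanh(atanh r ± 1.96/√(n − g − 3)) with g = 1 control variable; the choice
of n − g − 3 rather than n − 3 degrees of freedom is this package's
documented convention (at the cohort sizes involved the two are
indistinguishable).

### Numerical choices in the scan

* Index values inside the scan are formed in log space as
  exp(log w − p·log h) with per-power mean-centering of the log; for |p| up
  to 50 the direct power h^p would overflow double precision (for height in
  cm) or lose accuracy. The centering rescales the index by a positive
  constant per power, which is invisible to correlations.
* Grid powers are stored as exact integer hundredths (k/100), so grid
  points carry no accumulated floating-point drift and selected powers are
  exact two-decimal values.
* The zero crossing is reported as the grid point minimizing |r|, not an
  interpolated value, matching the two-decimal reporting convention of the
  field; a flag records whether a sign change actually brackets the
  optimum. Ties break toward the smaller power.
* If the index has (numerically) zero residual variance at some power —
  which happens exactly at the true exponent of a noise-free allometric
  cohort — its covariance with every measure is zero and the correlation is
  reported as 0 with a warning. The standalone `partial_corr` keeps the
  strict contract and raises on zero residual variance instead.

## Synthetic cohort model

Real cohort data of this kind is access-controlled, so the package ships a
generative model whose *marginal* distributions mimic a large middle-aged
UK population cohort and whose ground truth is known:

* height ~ truncated Normal (bounds 1.2–2.2 m); age ~ truncated Normal on
  [40, 70] years;
* log(weight) = log a + p_true·log(height) + b_age·(age − mean age) + ε,
  with ε ~ N(0, σ_w²) independent of height — so the population's true
  scaling exponent is the parameter `p_true` (defaults: 1.4 female-like,
  1.8 male-like, near the exponents such analyses report);
* body-fat % is linear in age and in the standardized weight residual ε/σ_w
  (so relative weight, not height, carries the fatness signal), truncated
  to (3, 75); fat mass = BF%·weight/100, fat-free mass the complement;
* waist and hip circumference are linear in fat mass plus noise, floored at
  40 cm; relative sitting height ~ truncated Normal, chosen so the 2.5% and
  97.5% quantiles land near the 0.50/0.55 stratum boundaries used in the
  screening tables;
* categorical covariates (ethnicity, education, smoking, alcohol) are drawn
  from fixed population frequencies and carry no biological signal: they
  exist to exercise covariate-adjustment plumbing.

Calibration is analytic, in `GeneratorParams.from_marginals`: the marginal
weight CV fixes the total log-scale variance; subtracting the height and
age contributions leaves σ_w (≈ 0.186 for the female-like preset). The
same decomposition sets the BF% and circumference noise SDs from their
total-SD targets. Female-like targets: height 162 (6.3) cm, weight
71.4 (14.0) kg, BF% 36.6 (6.9), WC 84.7 (12.5) cm, hip 103 (10.3) cm, age
56.3 (8.0); male-like: 176 (6.8) cm, 86.0 (14.2) kg, BF% 25.3 (5.7), WC
97.0 (11.2) cm, hip 103 (7.5) cm, age 56.7 (8.2). Truncated-normal
sampling is by rejection, so the bounds are honoured exactly.

Mortality is exponential: per-subject hazard
λ·exp(b_age·(age − mean) + b_idx·z) with z the within-cohort z-score of the
conventional index, administratively censored at 12 years. Defaults
(λ = 1.1×10⁻³/y female, 1.9×10⁻³/y male; b_age = 0.085/y; b_idx = 0.1/SD)
give event fractions of roughly 1.3–2.3% over follow-up, of the order seen
in such cohorts. The constant baseline gives closed-form event fractions
for testing; the Cox stage is semiparametric and indifferent to it.

**What the generator does not emulate.** Only marginals and a simple
dependence skeleton are calibrated; the full weight–height–fat covariance
structure of real populations is not reproduced (nor reported anywhere to
calibrate against). Consequently the *correlation values* the pipeline
prints on synthetic data (e.g. r ≈ 0.7 between index and BF%) are not
expected to match values from real cohorts (≈ 0.86); what is preserved —
and what the tests verify — is the *structure*: the ground-truth exponent
is recoverable, the height-criterion correlation is zero by construction,
the weight-criterion maximum is exactly one, and screening/survival
behave consistently between two formulas. There is no measurement-method
difference (bioimpedance vs absorptiometry), no ethnicity-specific body
composition, and no secular or cohort effects.

## Screening evaluation

High body fat is defined by the strict rules BF% > 35 (females) and
BF% > 25 (males). Discrimination is the rank-based AUC (Mann–Whitney
U/(n₁n₀), ties counted ½), which equals the ROC area of a one-predictor
logistic model because the fitted probability is monotone in the score —
an equality asserted in the tests rather than assumed. Operating cutoffs
maximize the Youden index over candidate cutoffs at midpoints between
consecutive distinct scores (plus ±∞), with the explicit classification
convention "index ≥ cutoff → predicted high" and ties broken toward the
smallest cutoff. Cutoffs, the selected exponent and category thresholds
are all learned on the training partition and frozen before test-set
evaluation.

Relative-sitting-height thirds are cut at the per-sex 2.5% and 97.5%
empirical quantiles (linear interpolation) of the evaluation cohort. If
the two quantiles coincide (degenerate distribution) everyone is assigned
to the middle stratum with a warning.

Ordinal category transfer between formulas uses quantile matching: each
new-formula threshold is the empirical quantile of the new index at the
cumulative fraction of training subjects below the corresponding old
threshold (old thresholds default to the standard 18.5/25/30 bands;
binning is left-closed, boundary values go up). This preserves training
marginal category frequencies to within 1/n. Quantile matching is this
package's documented choice of transfer method.

## Survival evaluation

Index values are grouped into fifths (cutpoints at the 20/40/60/80
empirical percentiles; a value equal to a cutpoint joins the lower fifth;
lowest fifth is the reference) and entered as indicators in a Cox
proportional-hazards model adjusted for age, deprivation score and the
categorical covariates (reference level = first declared level; "unknown"
is an ordinary level). Fits are separate per sex.

The Efron-tie-corrected log partial likelihood is maximized by Newton
iteration with step-halving until the score sup-norm falls below 10⁻⁸
(at most 50 iterations); non-convergence and separation (any |coef| > 20)
are errors, not silent results. Standard errors come from the inverse
observed information; hazard-ratio CIs are Wald, exp(coef ± 1.96·SE). The
likelihood, score and information are implemented directly (one O(n p²)
pass over subjects sorted by time) so they can be verified against central
finite differences, against the Breslow form in the absence of ties, and
against an independent survival fitter — those checks live in the test
suite, which is also why the fitter is not delegated to a library. AIC is
−2·log PL + 2·(number of coefficients); the comparison between formulas
reports ΔAIC (new − old).

Indicator levels observed with no deaths (or only deaths), including an
event-free reference group of an indicator family, make the partial
likelihood monotone in the corresponding coefficients; `fit_cox` merges
such levels into the reference with a warning before fitting. This only
occurs at small cohort sizes or very low event counts.

## Pipeline and reproducibility

`run_full_analysis` wires the stages together: generate (or read) a
cohort, split 80/20 stratified by sex (per-sex test share within one
subject of the requested fraction), build the criterion table and select
the exponent on the training partition, evaluate screening and survival on
the held-out partition, and emit a JSON bundle plus delimited-text tables
with a manifest of seeds, grid and version. A single top-level seed spawns
per-stage seeds through NumPy's `SeedSequence`; identical configuration
yields byte-identical bundles (no timestamps enter the report).

### Problem sizes and defaults

The pipeline's default grid is −5.00..5.00 (step 0.01): anthropometric
exponents live well inside this range, the full ±50 grid being a
robustness statement rather than a practical search space (it remains
available via configuration). Default synthetic runs use 20,000 subjects
per sex; acceptance-level checks use 50,000-subject cohorts, twenty
replicate seeds for recovery/coverage studies, and a million-subject
brute-force scan as the population reference for the exponent estimator.
At those sizes the height-criterion estimate recovers the generator's
ground truth with |bias| ≤ 0.05 and SD ≤ 0.05, and noise-free cohorts
recover it exactly to grid resolution.

## Known limitations

* The generator's calibration targets marginals only; absolute correlation
  levels, AUCs and hazard ratios on synthetic data are internally
  consistent but not comparable to values from any real cohort.
* The exponential mortality model has no competing risks, delayed entry or
  time-varying effects, and the Cox stage performs no proportional-hazards
  diagnostics.
* Fisher-z intervals assume approximate bivariate normality of residuals;
  with n in the tens of thousands the intervals are extremely narrow and
  the approximation is immaterial to selection.
* Allometric log-log regression is provided only as a cross-check utility
  (`allometric_exponent_loglog`); the selection method is purely
  correlation-criterion based.
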