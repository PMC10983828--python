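# Methods

This note documents the statistical model behind `hbref`, its defaults, the
numerical conventions that are frozen in code, and what the synthetic
validation does and does not demonstrate.

## Reference-sample derivation

The target estimand is a lower centile (5th primary, 2.5th secondary) of
haemoglobin (g/L) in an apparently healthy population. Because health is
unobserved, the reference sample is assembled *posteriori* by exclusion:

* **Laboratory criteria are mandatory.** A record missing haemoglobin,
  ferritin or CRP is excluded outright. Iron deficiency: ferritin strictly
  below 12 µg/L (age < 5 y) or 15 µg/L (otherwise). Inflammation: CRP
  strictly above 5 mg/L (the CRP unit is mg/L throughout). Elevated
  ferritin — a marker of inflammation or liver disease — excludes above
  200 µg/L (males and under-18s) or 150 µg/L (adult females); these ceilings
  are configuration, not constants, since guideline values differ between
  laboratories. An optional MCV floor (73 fL at 6–23 months, 75 fL at 24–59
  months) is off by default and switched on as a sensitivity variant.
* **Clinical criteria exclude only when affirmed.** A flag that is missing
  is not evidence of disease, so it never excludes — with one exception:
  pregnancy status must be *known* to be negative for a female non-pregnant
  group, because an unrecognised pregnancy shifts haemoglobin materially.
  This missing-status rule is applied to every female group that excludes
  pregnancy (adolescent and adult alike). Altitude strictly above 750 m
  excludes; missing altitude does not.
* **Outliers.** Tukey's inner fences (k = 1.5) with linear-interpolation
  quartiles, applied once to the haemoglobin of the survivors of each
  group-level reference sample. Fences need n ≥ 4.

Steps run in a fixed, documented order (group assignment → laboratory →
clinical/altitude → outliers) and each record is counted at its first
failing step, so the waterfall columns always chain
(`n_after = n_before − n_excluded`). The *kept set* is order-invariant
between the laboratory and clinical blocks; only the per-step attribution
depends on order.

Age groups use half-open intervals `[lo, hi)` in fractional years (months
divided by 12), so a child exactly 24 months old belongs to the 24–59-month
group. Sex-shared groups exist only below age 12; from adolescence the
groups are sex-specific, and pregnancy forms its own trimester groups at
ages 18–45.

## Discrete centiles

**Parametric Gaussian centile.** With sample mean x̄ and sd s,

    q̂_p = x̄ + z_p·s,     SE(q̂_p) = s·√(1/n + z_p²/(2(n−1))),

with z_0.05 = −1.6449, and a normal-approximation CI at the 90% level that
laboratory-standards guidance recommends for reference limits. Normality is
checked (Shapiro–Wilk plus skewness/kurtosis) but is advisory: a failed
check annotates the estimate and never switches the estimator, since no
principled fallback is defined for this design. A minimum sample size
(default 40, configurable) gates every estimate; smaller samples raise an
`InsufficientDataError` rather than emit an unstable number.

**Survey-weighted centile.** For complex-survey sources the point estimate
is the intercept of an intercept-only quantile regression with the survey
weights — which is mathematically the weighted p-quantile, and is computed
as such. The frozen tie convention: sort values, accumulate weights, return
the first value whose cumulative weight reaches p·W; when p·W lands exactly
on a boundary (relative tolerance 1e−9) return the midpoint of the adjacent
values. Any value returned this way minimises the weighted check loss.
Variance comes from a stratified survey bootstrap: each replicate resamples
n_h − 1 PSUs with replacement within stratum h and rescales weights by
m·n_h/(n_h − 1) (Rao–Wu), the SE is the sd of the B = 1000 replicate
quantiles, and the CI is estimate ± z·SE. A stratum with a single PSU is an
error with advice to collapse strata. The unweighted parametric centile of
the same records is always available as the sensitivity companion.

## Pooling

Per-source estimates within a group are pooled by fixed-effects
inverse-variance weighting (SE = 1/√Σw), which is the primary model on the
view that sources estimate a common healthy centile; DerSimonian–Laird
random effects (τ² = max(0, (Q − df)/C)) is the sensitivity model and
collapses to fixed when Q ≤ df. Q and I² = max(0, (Q − df)/Q) are reported
for both models so heterogeneity is visible even under the fixed model.
Forest tables carry per-source rows, the pooled row, relative weights, and
the current WHO cutoff for the group as a reference line (configuration
data). No graphics are rendered.

## Continuous centile curves

Two stages. First, the *mean* of haemoglobin against age is modelled by
fractional polynomials: powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, power 0
meaning ln x, a repeated power p contributing x^p and x^p·ln x. Ages are
rescaled by their geometric mean before powers are applied (recorded as
`age_scale`; predictions are invariant to it). The Royston closed test runs
on Gaussian least-squares deviance n·ln(RSS/n): best FP2 vs null on 4 df,
vs linear on 3 df, vs best FP1 on 2 df, each at α = 0.05 (the same α as the
interaction test; the search covers all 8 FP1 and 36 FP2 multisets, max
degree 2, sex as the only covariate). When sex is supplied its main effect
is always in the model, and a likelihood-ratio test compares
{FP(age) + sex} with {FP(age) + sex + sex×FP(age)} on df = number of FP
terms; the interaction is retained when p < 0.05.

Second, quantile regression at the target level is fitted on the selected
transform (statsmodels `QuantReg`, no survey weights — sources are pooled
as individuals). Predictions cover a uniform grid within the observed age
range only (default step 0.1 y; no extrapolation), and 90% bands are
bootstrap-percentile intervals from B = 1000 case-resampling replicates. A
replicate whose fit fails to converge is redrawn and counted, capped at 5%
of B. Degenerate constant input yields a flat curve with zero-width bands.
The point estimate is clipped into its own band so pointwise containment
holds even at percentile-interpolation edge cases.

## Synthetic cohorts and ground truth

The generator emulates the *statistical structure* of multi-source
threshold studies, not any real survey's empirical distributions:

* Healthy mean: μ(age, sex) = 120 + 4·ln(age) g/L below age 12 (sexes
  shared), a linear ramp from 12 to 18 y to adult levels of 149.5 (male) /
  134.5 (female) g/L, flat thereafter; sd 9 g/L. These values place the true
  5th centiles in the ranges reported for healthy populations
  (about 105 g/L in infancy to 135 g/L in adult men) and create a genuine
  adolescent sex divergence for the interaction test to find.
* Conditions: iron deficiency (prevalence 0.15), inflammation (0.10), and
  clinical flags (chronic illness 0.08, current smoking 0.15, recent
  hospitalisation 0.03) each depress haemoglobin by 10 g/L by default —
  large enough that skipping the filter visibly biases the centile low.
  Ferritin is lognormal (healthy median 60 µg/L, σ_log 0.5; deficient median
  6 µg/L), CRP lognormal (healthy median 0.6 mg/L, σ_log 0.8; inflamed
  median 20 mg/L). The biomarker distributions overlap the exclusion
  thresholds slightly, as real ones do, so a small fraction of healthy
  individuals is excluded (harmless) and a small fraction of affected
  individuals leaks through (a slight downward pull on estimates).
* Survey design: per-source strata and PSUs, a shared PSU effect with
  ICC 0.02 carved out of (not added to) the marginal sd so ground truth is
  unchanged, and lognormal weights (σ_log 0.3) around each stratum's inverse
  sampling fraction.
* Missingness defaults: 1–2% for analytes, 10% for MCV, 5% for flags, 2%
  for pregnancy status.
* Pregnancy: female-only adult sources with trimester mean offsets −8/−14/
  −12 g/L from the adult female level.

Ground truth stores per-group μ, σ and the exact Gaussian centiles
μ + z_p·σ. For groups whose age span crosses a sloped region of the mean
curve, μ is averaged over a uniform age distribution and the marginal
distribution is a normal location mixture, so the stored centile is exact
only where the mean is flat (adult and pregnancy groups); validation
coverage studies therefore use adult groups.

What passing tests show: the estimators are algebraically correct, the
survey bootstrap and the parametric CI are calibrated under the generator's
assumptions, the model selection has its nominal operating characteristics,
and the exclusion machinery recovers a known healthy truth. What they do
not show: robustness to real-data features the generator omits — digit
preference and analyser rounding, non-Gaussian healthy tails, informative
weights, age-dependent condition prevalences, and between-source
heterogeneity in measurement method.

## Numerical conventions and edge cases

* Quartiles and percentile bands use linear interpolation throughout.
* Strict inequalities at every exclusion threshold (a ferritin of exactly
  15 µg/L is kept).
* Weighted-quantile boundary ties resolved by midpoint (see above);
  detection at relative tolerance 1e−9.
* An RSS of a numerically perfect fit is floored at 1e−12 before the log
  deviance, making deviance differences zero rather than NaN.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-task seeds from one master seed via `SeedSequence` and records
  them in the manifest. Identical config + seed reproduces byte-identical
  CSV artefacts.

## Known limitations

* Fixed-effects pooling of centiles assumes within-source normality drives
  the SEs; heavily skewed reference samples are flagged by the normality
  report but not re-modelled (no rank-based CLSI alternative yet).
* Tukey trimming of an exactly Gaussian sample removes ~0.7% of mass and
  slightly shrinks s; with the generator's slight contamination leak the two
  effects roughly offset, but end-to-end CI coverage sits near the lower
  edge of nominal, and on cleaner data the parametric centile after
  trimming would be mildly anti-conservative.
* The survey bootstrap estimates the SE on roughly (number of PSUs −
  number of strata) degrees of freedom; with very few PSUs (say 10 in
  total) the SE is so variable that the prescribed normal-approximation
  90% interval covers only ~83–84% of the time, while from about 20 PSUs
  upwards coverage is nominal (~88–90% in simulation). Designs with
  few PSUs would need a t-quantile or a percentile interval, neither of
  which this pipeline applies.
* No smoothing or monotonicity constraint on continuous curves; no
  LMS/GAMLSS alternative.
* Missing analytes are never imputed, and BMI flags must be computed
  upstream.
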