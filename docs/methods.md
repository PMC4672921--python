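# Methods

This note documents the statistical model behind `septikit`, the defaults that
matter, the numerical conventions, and what the synthetic-data tests do and do
not demonstrate.

## The classifier family

The package builds classifiers of the form

```
score(s) = σ₁ · (log2 I_A(s) − log2 I_B(s)) + σ₂ · (log2 I_C(s) − log2 I_D(s))
```

with orientations σᵢ ∈ {+1, −1} and four distinct genes. Working with
log-ratios rather than absolute expression has two practical virtues: the score
is invariant to any per-sample shift on the log scale (i.e. to multiplicative
normalisation errors on the linear scale), and a pair of oppositely regulated
genes concentrates twice the class signal in one feature. Log base 2 is used by
microarray convention; ranking and AUCs are invariant to the base (a base change
multiplies every feature by the same positive constant).

On the RT-qPCR side the same classifier is expressed in threshold cycles. With
the inverse linear relation `Ct = α − β·log2 I` (β > 0), the expression-scale
score maps to `−Ct₁ + Ct₂ − Ct₃ + Ct₄` up to the affine factor β, which is why
the Ct-score's coefficients are the sign-flipped ±1 pattern. The two scores are
affinely related on noise-free data; the test suite asserts this identity.

## Discovery: screening and greedy search

1. **Prefilter (optional).** Genes are ranked by oriented univariate AUC (ties:
   absolute standardized mean difference, then gene id) and the top `top_n`
   kept. This is a generic univariate stand-in for heavier wrapper-based
   enrichment; it only needs to keep signal genes in the pool, not rank them
   perfectly.
2. **Ratio screen.** Every unordered pair in the pool is evaluated once and
   oriented so its AUC ≥ 0.5. The default screening objective is the
   **binormal (moment-based) AUC** `Φ((μ₁−μ₀)/√(s₁²+s₀²))`: it is a smooth
   function of group moments with far lower sampling variance than the
   empirical midrank estimate, which matters when maximising over hundreds or
   thousands of candidates. The empirical Mann–Whitney objective is available
   via `objective="empirical"`; final performance evaluation always uses the
   midrank estimator.
3. **Greedy pair search.** The best ratio seeds the model; the partner is the
   candidate among the `pool_k` next-ranked ratios that maximises the AUC of the
   summed score, subject to four-distinct-genes. `pool_k` defaults to **5**,
   deliberately small: each additional candidate is another draw in a
   maximisation over noise, so wide pools inflate selection optimism and —
   measured on synthetic cohorts — *reduce* the probability of recovering a
   planted signature. If a "hub" gene dominates the ranking and no windowed
   candidate is gene-disjoint from the seed, the single highest-ranked
   admissible candidate further down the list is considered instead. If no
   admissible partner reaches the seed's own AUC, the classifier degenerates to
   the single seed ratio with a warning.

Training AUCs from this search are optimistic by construction (they are the
maximised objective); the test suite contains an explicit check that the
optimism gap on pure-noise data shrinks as the cohort grows. The package also
offers a seeded subsample-stability report (`subsample_stability`) as a
lightweight alternative to full repeated re-discovery.

## Scoring, bands, and probabilities

* **Binary cutoff.** `score ≥ 3.100` is called positive; the boundary belongs to
  the positive class because the cutoff is chosen to favour sensitivity.
* **Bands.** Edges default to (4, 6, 9) with half-open `[lo, hi)` intervals so
  the bands partition the score axis; printed labels like "4–6" are ambiguous at
  exact edges, and users relying on boundary behaviour should note the
  convention.
* **Likelihood ratios.** Per band, `LR = (cases in band / total cases) /
  (controls in band / total controls)`, with no continuity correction: a band
  with cases but no controls yields LR = ∞ (post-test probability 1), a band
  with no cases yields 0. Log-method (Simel) CIs for the 2×2-based LR± add 0.5
  to every cell only when some cell is zero.
* **Post-test probability.** `posterior = odds·LR / (1 + odds·LR)` with
  `odds = p/(1−p)`. When the pre-test probability equals the cohort prevalence,
  the band-weighted average of posteriors reproduces the prevalence exactly
  (law of total probability); the suite asserts this to 1e-12.
* **Platform harmonisation.** Scores from non-reference PCR chemistries are
  mapped by per-platform affine shifts `offset + slope·score` supplied in the
  config; shifts are never hard-coded and default to the identity for the
  reference chemistry.
* Scores are reported to 3 decimals, matching the cutoff's precision.

## Evaluation statistics

* **AUC** is everywhere the midrank Mann–Whitney probability; a property test
  checks exact agreement with exhaustive pair counting. Bootstrap CIs resample
  within class (2000 replicates, percentile 2.5/97.5); degenerate replicates are
  retained since the midrank estimator stays defined.
* **Binormal ROC** is fitted by the method of moments on raw scores (no
  transform): `a = (μ₁−μ₀)/s₁`, `b = s₀/s₁`, `AUC = Φ(a/√(1+b²))`. Moments are
  deterministic and closed-form; zero within-group variance is an error that
  points the user to the empirical method.
* **DeLong's test** uses placement values with midranks; paired comparisons use
  the cross-marker placement covariance, unpaired comparisons the sum of
  per-marker variances. Identical inputs return p = 1 by convention (the
  variance of the difference is zero). The variance tracks the delete-one
  jackknife (asserted within 10% in the suite), and on a small fixed paired
  instance the p-value agrees with a 10⁵-swap permutation oracle within 0.02.
  The normal approximation is less reliable for very small, strongly
  discordant samples; the permutation route is the fallback there.
* **Whole-curve permutation test.** The statistic is the mean absolute TPR
  difference between the two empirical ROC curves over the control-rank FPR
  grid (a Venkatraman-style whole-curve distance, sensitive to crossing curves
  with equal AUCs). The null is generated by per-subject marker swaps (paired)
  or by reshuffling subjects between markers within each disease class
  (unpaired; equal group sizes per class are required so the two curves share a
  grid). `p = (exceedances + 1)/(reps + 1)`, 2000 permutations by default;
  type-I error is verified by simulation to sit near the nominal 5%.
* **Proportion CIs** are Wilson score intervals — well-behaved at 0 and 1 —
  which can differ in the second decimal from logistic-regression-based
  intervals other software reports.
* **NRI** for paired binary tests: NRI+ is the sensitivity difference among
  cases, NRI− the specificity difference among controls, with inference from
  the paired-proportion (discordant-pair) variance.
* **Distribution comparisons**: two-sided KS for cumulative distributions;
  Welch's t or Wilcoxon rank-sum for frequency distributions, chosen in `auto`
  mode by a Shapiro–Wilk screen on both samples at α = 0.05.
* **Balance check**: a case:control split is flagged unbalanced when the
  observed count falls outside the exact equal-tailed 95% interval of
  Binomial(n, ½) — e.g. 74:31 is unbalanced, 52:48 is not.
* All tests are two-sided with α = 0.05; every resampled result is reproducible
  bit-for-bit given the seed.

## Clinical covariate modelling

Covariates are screened individually by single-predictor logistic Wald p ≤ 0.05
(perfect separation counts as significant; constant or near-empty covariates
are dropped with a warning). Forward greedy selection then adds, at each step,
the covariate maximising mean test AUC over `n_repeats` (default 50) seeded
stratified 1:1 train/test splits, stopping when nothing improves. Inside each
training fold, covariates are median-imputed and z-scored using training-fold
statistics only, and the logistic fit carries a tiny ridge penalty (λ = 1e-6 on
standardized covariates) purely so separated folds converge; forced-in
parameters enter first regardless of rank and forced-out parameters never
enter. The accepted-step CV-AUC sequence is non-decreasing by construction.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not real
transcriptomes:

* **Expression model.** Gaussian log2 intensities, background genes identical
  in both classes (SD 1.0 around baseline 8.0); the four signature genes carry
  per-gene baselines (9/8/9/8) and class shifts of ±1.5 log2 units (= 1.5 SD)
  in cases — two up (*PLAC8*-like, *LAMP1*-like), two down (*PLA2G7*-like,
  *CEACAM4*-like). Default cohort 74 cases / 31 controls, 50 genes.
* **Ct model.** `Ct = 30 − 1.0·log2 I + N(0, 0.25)`, clipped to (0, 50].
* **Validation cohorts.** Labels drawn at prevalence 0.30 with a 0.13
  "possible" fraction. "Possible" samples draw their expression from a
  case/control mixture whose weight defaults to the cohort prevalence, so their
  score distribution coincides with the pooled known-status distribution — the
  design expresses the finding that ambiguous patients are indistinguishable
  from the pooled cohort on the score alone. The weight is exposed in `SimSpec`
  for sensitivity analyses (e.g. a fixed 50/50 mixture makes the ambiguous
  group detectably score-shifted at large n). Covariates: a PCT-like
  log-normal marker (latent class effect 1.2 SD) and an APACHE-like severity
  score (0.5 SD, i.e. deliberately weak — severity should not explain the
  molecular signal).

What passing tests on these cohorts show: the pipeline recovers a planted
signature of realistic effect size at realistic cohort sizes, estimators agree
with oracles, and probability identities hold. What they do not show:
performance on real data, where genes are correlated, effects are
heterogeneous, class distributions are skewed, and batch effects exist. No
claim about real-cohort AUCs follows from the synthetic results.

## Problem sizes and defaults used in checks

Simulation-based checks run at the cohort sizes the defaults encode (74/31
discovery, 300–400-sample validation draws), with 20 seeds for signature
recovery, 200 null datasets × 500 permutations for the curve-test calibration,
400–1000 null datasets for t-test calibration, 1000 random instances for the
pair-counting identity, and 10⁵ permutations for the DeLong oracle — sizes
chosen to make Monte-Carlo noise small relative to the asserted tolerances.

## Known limitations

* Microarray preprocessing (probe summarisation, RMA/quantile normalisation,
  array-level QC) is upstream and out of scope; expression input is assumed
  normalised, and linear-scale input is log2-converted on request.
* The RNA QC gates implement fixed published-style thresholds (yield ≥ 2 ng/µl
  for RT-qPCR; A260/A280 > 1.6 and integrity > 5 for microarray) and nothing
  probe-model-based.
* The whole-curve permutation test's unpaired mode requires equal per-class
  group sizes; for unequal cohorts use DeLong.
* Platform shift coefficients are user-supplied configuration; the package
  ships only the identity.
* LR confidence intervals use the log method; software built on the Gu–Pepe
  regression approach may print "not calculable" where this package still
  returns an interval (with the 0.5-cell correction noted above).
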