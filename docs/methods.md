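# Methods

## Estimand and data structure

The analysis contrasts two starting doses of secukinumab (300 mg vs 150 mg)
in adults with active psoriatic arthritis followed over six visits (baseline,
weeks 4, 16, 28, 40, 52).  The primary outcome is the reduction of the PsAID
score (0–10, 10 worst) from baseline to Visit 3, with Visit 4 as fallback
when Visit 3 is missing; positive values mean improvement.  The estimand is
the conditional average treatment effect θ(x): the extra PsAID reduction a
patient with baseline covariates x would obtain from starting on 300 mg
rather than 150 mg.

Dose assignment in routine care is severity-driven, so identification rests
on conditioning on the declared confounder set W = {baseline PsAID, BMI,
PASI, months of TNF-α-inhibitor pretreatment, number of prior biologics,
plaque psoriasis}; the remaining covariates X (age, sex, CRP, BDI, PhGA,
PGA, SPI-II, smoking) are treated as outcome-only.

## Cohort engineering rules

* Treatment must have started no earlier than 4 weeks before baseline.
* The outcome must be recorded at baseline and at Visit 3 (else Visit 4).
* The dose must be recorded and unchanged from baseline through the endpoint
  visit actually used.  We interpret the stability window as ending at that
  endpoint, not at week 52.
* Feature columns with ≥ 50 % missing values (boundary inclusive) are
  dropped; Y, T and W columns are exempt (warned, retained).  Gaps in
  retained features are median-imputed (mode for categoricals) with
  `*_was_missing` indicator columns, since the nuisance learners cannot take
  missing values; the source analysis does not state its imputation, so this
  is our choice.
* PsAID burden categories: remission < 2, low ∈ [2, 3], moderate ∈ (3, 6),
  high ≥ 6.  "Effective treatment" is a reduction ≥ 3 points.
* Smoking is dummy-coded with the active smoker as reference.

## Estimators

**Stage 1.** m̂(x) = E[Y | X, W] and ê(x) = P(T = 1 | X, W) are predicted
out-of-fold with k = 5 treatment-stratified cross-fitting folds.  Default
learners are shallow histogram gradient-boosted trees (depth 3, 150
iterations); a regularized-linear pair (ridge / logistic) is available and is
used throughout the Monte-Carlo harnesses for speed and because both true
nuisance surfaces are near-linear there.  Propensities are clipped to
[0.01, 0.99] — overlap in real registries is imperfect and extreme weights
otherwise dominate the IPTW variance.

**Stage 2.** Weighted least squares of the outcome residual on the treatment
residual interacted with φ(x) = (1, modifiers…), with HC1 sandwich standard
errors and normal p-values.  An intercept-only basis reduces to the
partially linear ATE and coincides with the closed-form moment ratio
Σ T̃Ỹ / Σ T̃² (both routes implemented, cross-checked in tests).  Collinear
basis columns are dropped greedily with a warning.  The global
coefficient table (forest-plot analogue) uses all features, z-scored, as
modifiers and sorts by ascending p-value.  A causal-forest Stage 2 is a
documented extension point, not implemented; subgroup heterogeneity comes
from the linear θ̂(x) plus the tree below.

**IPTW.** Hájek (normalized-weight) estimator with weights 1/ê and
1/(1 − ê); SE by the weighted-mean delta method.  With constant propensities
it reduces exactly to the naive contrast.

**Heterogeneity tree.** Greedy recursive partitioning of θ̂(x) over baseline
covariates; each split maximizes (n_L n_R / n²)(mean_L − mean_R)², the
between-group sum of squares over n², which is one standard
operationalization of "maximize heterogeneity between children".  Candidate
thresholds are midpoints of sorted unique values (one-level-vs-rest for
categoricals); rows satisfying the condition go left; ties break by
covariate name, then lowest threshold; defaults min_leaf = 50,
max_depth = 3.  Splitting stops when no split improves the score beyond
floating-point noise.  The tree partitions the fitted θ̂ rather than
refitting the causal model per node, keeping subgroup estimates consistent
with the global fit.

**Counterfactuals and policies.** For a patient observed under dose T with
outcome Y, the predicted outcome under the opposite dose is Y ± θ̂(x);
counterfactual PsAID scores are clamped to the instrument range [0, 10].
Burden-shift matrices cross-tabulate observed vs counterfactual categories
for low-dose patients; percentages are per row, rounded half away from zero.
A threshold policy recommends 300 mg iff θ̂(x) > τ (strict inequality), with
τ ∈ {0, 0.2, 0.5} PsAID points by default, reflecting that the cheaper dose
is preferred unless the predicted gain is material.

## Synthetic cohort generator

The registry behind the original analysis is not public, so the generator
emulates its published structure and serves as the testbed with known ground
truth:

* **Marginals** follow the published baseline table: PsAID ~ truncated
  normal(5.2, 2.1) on [0, 10], BMI ~ truncated normal(29.4, 6.1), CRP
  lognormal matched to mean 8.4 / SD 13.7 mg/L, BDI/PhGA/PGA/SPI-II/PASI
  truncated normals on their instrument ranges, Bernoulli sex and plaque
  psoriasis, three-level smoking, Poisson prior-biologic count,
  zero-inflated-exponential months of TNFi pretreatment.  Families are our
  modelling choice; the table reports only means and SDs.  Baseline PsAID
  and BDI share a Gaussian copula correlation of 0.45 (disease impact and
  depression are moderately correlated in this population).
* **Assignment** is logistic in baseline PsAID, BMI, PASI, prior-biologic
  count and plaque psoriasis — all members of W, so the estimand stays
  identifiable by construction.  Coefficients are mild (e.g. 0.10 per PsAID
  point) so that the between-arm baseline severity gap is a few tenths of a
  point, as in the published cohort, and the intercept centres the high-dose
  share near 1/2.
* **Outcome.**  Visit-3/4 PsAID = baseline − [response(x) + θ(x)·T + ε],
  clamped to [0, 10].  response(x) = 0.22·PsAID₀ + 0.022·BDI₀ is the
  prognostic (dose-independent) regression-to-improvement; θ(x) =
  0.14 + 0.38·1[BMI > 32.5] PsAID points is the true effect; ε ~ N(0, 1)
  with noise_sd = 1.0 as default measurement noise, chosen so that the
  instrument floor is rarely hit and the nominal θ(x) is, to a very good
  approximation, the true CATE of the generated data.  Under these defaults
  the population naive contrast is ≈ 0.38 against a true ATE of ≈ 0.26 —
  the same direction and similar magnitude of confounding bias as the
  published 0.37 vs 0.236.
* **Missingness** is MCAR per column at rates spanning the published range
  (38 % PsAID … 76 % PASI), with an optional outcome-dependent (MNAR)
  variant that masks worse scores more often; identity and dose columns are
  never masked.  A 5 % per-patient dose-switching rate exercises the
  dose-stability exclusion rule in end-to-end runs.
* Hidden `_true_theta`, `_true_response` and `_true_propensity` columns are
  carried for evaluation only and written to a separate file.

**What the generator does not emulate:** informative dropout, visit-date
jitter, within-patient serial correlation beyond the shared baseline,
adverse events/retention, multi-stratum registries, or measurement floor
effects on secondary scores.  Passing tests therefore demonstrate estimator
correctness under severity-confounding with known truth, not fidelity to
every feature of the real registry.  In particular the share of
"effectively treated" patients (reduction ≥ 3) is smaller in the synthetic
cohort than in the published one because the synthetic outcome noise is
deliberately modest.

## Monte-Carlo harness sizes

Parameter recovery uses 20 replicates of n = 2000 patients (missingness and
switching disabled so the analysis sample equals the cohort and the exercise
isolates estimator behaviour); the IPTW-vs-naive error comparison uses 20
replicates of n = 5000, where estimator noise no longer masks the ~0.12-point
naive bias; the CI-coverage check uses 100 replicates of n = 400 with linear
learners.  These sizes make the checks sharp while keeping a full run of the
suite inexpensive.

## Numerical choices and degenerate inputs

* Welch (unequal-variance) t-test; identical constant samples return
  (t = 0, p = 1), other degenerate samples raise.
* 95 % CIs are mean ± 1.96·SE throughout.
* Fold assignment guarantees overall fold sizes differ by ≤ 1 and both
  treatment classes appear in every training fold (else abort).
* Percent rounding is half-away-from-zero to integers.
* Zero-row shift-matrix rows yield NaN percentages (flagged, not an error).
* Byte-identical artifacts: all randomness flows from explicit integer
  seeds; summary JSON is sorted-key serialized, and every artifact embeds
  the seed and a hash of the scientific configuration.

## Known limitations

* Confounder adjustment is only as good as the declared W; the generator
  confounds only through W by design, whereas real registries may not offer
  that guarantee.
* Linear Stage 2 restricts heterogeneity to the chosen basis; effects that
  modify outside φ(x) are projected onto it.
* Robust SEs ignore the sampling noise of the heterogeneity tree; leaf
  CATEs carry no confidence intervals.
* Real-cohort headline figures that depend on the non-public registry
  (e.g. its exact policy fractions) are reproduced only as arithmetic
  identities on published summary numbers, not re-estimated.
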