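# psadose

Causal machine learning for biologic dose-escalation decisions in psoriatic
arthritis (PsA).

In routine care, patients with more severe PsA are preferentially started on
the higher 300 mg secukinumab dose, so the raw outcome difference between the
300 mg and 150 mg groups mixes the true dose effect with
confounding-by-indication.  This package estimates the **conditional average
treatment effect (CATE)** of 300 mg vs 150 mg on the reduction of the PsAID
score (Psoriatic Arthritis Impact of Disease, 0–10, 10 worst) from
observational visit-level data, finds the subgroups that benefit most, and
simulates counterfactual dose switches and threshold dosing policies.  It is
aimed at biostatisticians and pharmacoepidemiologists working with registry
data.

## Model

Let `Y` be the PsAID reduction from baseline to Visit 3/4 (positive =
improvement), `T ∈ {0, 1}` the starting dose (150/300 mg), `W` declared
confounders (baseline PsAID, BMI, PASI, months of TNF-α-inhibitor
pretreatment, count of prior biologics, plaque psoriasis) and `X` the
remaining outcome-only covariates.  Double machine learning proceeds in two
stages:

1. **Cross-fitted nuisances** — `m̂(x) ≈ E[Y | X, W]` and the propensity
   `ê(x) ≈ P(T = 1 | X, W)`, each predicted out-of-fold over k = 5
   treatment-stratified folds; propensities are clipped to [0.01, 0.99].
2. **Residual-on-residual regression** —

   `Y − m̂(x) = [(T − ê(x)) · φ(x)]ᵀ β + ε`

   with a basis `φ(x) = (1, effect modifiers…)`, so `θ̂(x) = βᵀφ(x)` is the
   per-patient CATE and its mean the ATE.  Inference uses
   heteroskedasticity-robust (HC1) standard errors.

A Hájek IPTW estimator (same clipped propensities, no outcome model) serves
as the classical debiasing benchmark, and a greedy heterogeneity tree
partitions `θ̂(x)` into subgroups by maximizing the between-child score
`(n_L n_R / n²)(mean_L − mean_R)²`.

Because the underlying registry is not public, a **synthetic cohort
generator** with severity-driven dose assignment and a known ground-truth
effect `θ(x) = 0.14 + 0.38 · 1[BMI > 32.5]` PsAID points stands in for the
real data; every estimator is validated against that hidden truth.

## Worked example

```sh
python analysis/01_simulate.py --seed 1          # synthetic 1235-patient registry
python analysis/02_build_cohort.py               # eligibility + outcome engineering
python analysis/03_describe.py                   # group summaries, naive contrast
python analysis/04_fit_dml.py --seed 1           # double-ML fit + IPTW
python analysis/05_tree.py                       # subgroup heterogeneity tree
python analysis/06_policy.py                     # counterfactual shifts, policies
```

The fit step prints (seed 1):

```
average CATE (300 vs 150 mg): +0.313 PsAID points
  start_dose: +0.251 (SE 0.095, p=0.00845)
  bmi_high: +0.188 (SE 0.173, p=0.277)
IPTW ATE: +0.262 (SE 0.101)
ground-truth sample ATE: +0.270
```

The naive contrast on the same cohort is +0.444 points — inflated because
sicker patients both receive the high dose and improve more regardless of
dose.  Both causal estimates (DML +0.313, IPTW +0.262) move toward the
hidden true effect (+0.270).  The tree step then recovers the generator's
BMI split:

```
n=605  mean CATE=+0.313
  [bmi <= 32.5007] n=405  mean CATE=+0.251
  [bmi > 32.5007] n=200  mean CATE=+0.439
```

i.e. patients above BMI ≈ 32.5 gain roughly 0.19 PsAID points more from
escalation than those below.  `analysis/07_parameter_recovery.py` repeats
the whole exercise over 20 replicates and reports how often the Stage-2
coefficients land within 2 robust SEs of the true (0.14, 0.38).

The same pipeline is available as a CLI (`psadose simulate | build-cohort |
describe | fit | tree | policy | run`); `psadose run --config
configs/default.yaml` writes the full artifact bundle with a deterministic,
seed-stamped `summary.json`.

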