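# Methods

`paikit` implements a Personalized Advantage Index (PAI) analysis for a
two-arm randomized trial — cognitive therapy (CT) versus interpersonal
psychotherapy (IPT) for depression — with longitudinal BDI-II follow-up.
This note documents the statistical procedures, the synthetic-trial
generator that stands in for clinical data, the numerical choices, and the
known limits of what the test suite demonstrates.

## Outcome construction

Follow-up BDI-II scores on the schedule 7, 8, 9, 10, 11, 12, 24 months are
summarised per participant as the integral of an interpolating cubic spline
(the AUC, in BDI·months), interpreted as total symptom burden over the
17-month window.

**Boundary conditions and noise amplification.** The AUC is a fixed linear
functional of the seven scores, `auc = Σ w_j v_j` with `Σ w_j = 17`, and
the weights depend on the spline's boundary rule. On this uneven schedule
(a 12-month gap after six monthly visits) the cubic swings over the last
interval: not-a-knot or FMM boundaries give weights up to ±250, so
*independent* per-visit perturbations — measurement jitter, imputation
error, floor clipping — are amplified ~19× on the average-BDI scale, enough
to bury any plausible moderator signal once ~15% of outcome cells are
imputed. We therefore use *natural* boundaries (zero endpoint curvature),
whose weights stay within ±29 (amplification ~2.4×). The price is accuracy
on curved trajectories: the natural-spline AUC is exact for linear
trajectories on any schedule, and for smoother ones converges with knot
density (relative error on a pure cubic: 6.7% on the sparse 7-point
schedule, 2×10⁻⁹ with 500 knots). For bounded, noisy symptom scores the
robustness is worth far more than third-degree exactness; analyses feeding
cubic-spline AUCs on schedules like this one should check the weights
before trusting the summary.

For modelling, the AUC is residualized on baseline BDI-II by OLS (removing
chance baseline imbalance between arms); for reporting, the raw AUC is
divided by the 17-month span to give an "average follow-up BDI-II" in
familiar 0–63 units. Group means are reported on the raw (not residualized)
average-BDI scale, since residuals are mean-zero by construction and
uninterpretable as severities.

## Synthetic-trial generator

No clinical data ship with the package; `synthetic_trial.generate` draws
trials with known ground truth under these default conditions:

| parameter | default | rationale |
|---|---|---|
| n participants | 151 (76 CT / 75 IPT) | trial scale, 1:1 balanced randomization |
| covariates | 38, mixed kinds | post-screening battery size |
| block correlations | (4 vars, r=0.6), (4 vars, r=0.4) | correlated questionnaire blocks; below the 0.70 screening cut because the default set emulates *screened* survivors |
| planted predictor | binary (prevalence 0.25), effect 3.2 points/SD (0.4 residual SD) | prognostic history item, weakest of the planted variables |
| planted moderators | two Poisson(1.5) counts, interaction effects 6.4 and 4.8 points/SD (0.8 / 0.6 residual SD) | right-skewed event counts (life events, childhood trauma analogues) |
| outcome intercept / residual SD | 15 / 8 average-BDI points | mild-symptom follow-up severity with realistic spread |
| baseline BDI-II | Normal(25, 8), clipped to [0, 63] | moderate pre-treatment severity |
| baseline effect | 2 points/SD | prognostic baseline, removed by residualization |
| covariate / outcome missingness | 0.4% / 15.5% | typical attrition pattern, MCAR by default, MAR available |

Covariates are drawn from a latent Gaussian with block-equicorrelated
structure; counts arise by Poisson quantile transform, binaries by
thresholding, so block correlations survive (approximately) the
transformation. Effects apply to theoretically standardized covariates, so
effect sizes read as outcome points per covariate SD.

**Trajectories.** Each participant's realized average level is the linear
model value plus Normal(0, residual_sd) noise; the trajectory is a line
through the schedule with random slope (SD 0.15 points/month) centred so
its spline-AUC equals the realized level × 17 exactly. Per-visit jitter is
available (`visit_noise_sd`) but defaults to zero: given the ~19×
amplification above, independent visit noise of 1 BDI point would
contribute ~19 points of average-scale noise and swamp any plausible
moderator signal. BDI-II values are clipped to [0, 63] after generation
(clip counts logged); at default settings ~2–7% of cells touch the floor,
a realistic floor effect that slightly attenuates recovered coefficients.

What the generator does *not* emulate: non-linear symptom trajectories,
informative dropout, therapist effects, treatment-process variables, and
item-level questionnaire structure. Passing recovery tests therefore show
the pipeline works when its linear-model assumptions hold, not that the
clinical findings replicate.

## Missing-data imputation

`rf_impute` implements the iterative random-forest (missForest) scheme:
initialize missing cells at column means/modes, sweep columns in increasing
missingness order fitting a forest of each column on all others (observed
rows) and predicting missing rows, and stop when the stratified difference
statistic first increases (returning the previous sweep) or after 10
sweeps. Forests are scikit-learn `RandomForestRegressor`/`Classifier` with
100 trees and mtry = √p. The feature matrix holds outcome
change-from-baseline scores (month 3 included when present), all
covariates, and the arm indicator. Counts are imputed as continuous and
rounded to admissible values; binaries by classification forest. Accuracy
is validated by masking cells of a complete dataset and scoring NRMSE
(continuous) and PFC (categorical) on the masked cells only.

Expected accuracy depends entirely on how much cross-column structure the
data carry. On the default synthetic trial the forest clearly beats mean
imputation on continuous cells (NRMSE ≈ 0.2 vs 1.0), but most binary
covariates are independent noise by construction, so PFC sits near the
minority-class share (~0.25) — the best any imputer can do there. Strongly
inter-correlated questionnaire batteries in real data can yield far lower
PFC; a low PFC is a property of the data's redundancy, not of the
algorithm.

## Two-step variable selection

**Stage 1 — MOB forest.** Each tree fits `outcome ~ intercept + arm` in
every node and tests, for a per-tree random subset of √p covariates,
whether the node model's score contributions fluctuate along the covariate.
Numeric covariates use the trimmed sup-LM statistic on the covariate's sort
order; its asymptotic null distribution (sup of a squared standardized
2-dimensional Brownian bridge over a trimmed interval) has no closed form,
so quantiles were simulated once (200 000 paths, 2000-step grid; see
`scripts/make_suplm_table.py`) and shipped as a JSON table interpolated in
(trim, statistic). Binary covariates use a chi-square on per-level score
sums. P-values are Bonferroni-corrected over the candidates tested in the
node; a node splits when the adjusted minimum p < 0.10, at the point
minimising the children's residual sum of squares subject to ≥15
observations per child (defaults follow the stated tuning: 10 000 trees,
α = 0.10, minimum node 15). Nodes holding one arm only become leaves with a
mean-only model. Permutation importance is the out-of-bag MSE with a
covariate permuted minus with real values, averaged over the trees that had
the covariate available; the selection threshold is the absolute importance
of the lowest-ranking covariate.

Two properties of this design, established by simulation, temper
expectations:

- the lowest-rank threshold is itself a noisy order statistic, so under
  pure noise the selected set is *small on average* (usually 0–1 variables)
  but occasionally admits 2–3;
- the node model's instability test is sensitive to intercept instability
  as much as treatment-effect instability, so a strong prognostic variable
  can out-rank genuine moderators. With the default planted effects
  (predictor 0.4 SD, moderators 0.8/0.6 SD) a planted moderator ranks
  first in only ~60% of replicates — the binary predictor, whose full
  signal is captured by a single split in both arms, wins most of the rest.
  This is inherent to model-based recursive partitioning with a
  joint-parameter instability test, and is invariant to forest size
  (measured at 500 through 10 000 trees).

**Stage 2 — bootstrap backward elimination.** The stage-1 survivors enter
`outcome ~ Σ mains + arm + Σ (x × arm)`; on each of 1000 bootstrap
resamples, the least significant droppable term (p > 0.05) is removed
iteratively, honouring marginality (mains stay while their interaction
lives; intercept and arm are never dropped). Terms surviving ≥60% of
resamples are robust; a variable with a robust interaction is a moderator,
with only a robust main effect a predictor. Because the bootstrap resamples
the *same* trial, this procedure measures the stability of the original
sample's associations — chance associations at n=151 with ~76 candidate
terms are regularly confirmed as robust, so the robust set typically
contains the strong planted terms *plus* one or two idiosyncratic extras
(exact-recovery rate ~25–30% over seeded replicates, again invariant to
resample count). Users should read the robust set as a shortlist, not a
certificate.

## PAI computation and evaluation

The final model is OLS with the selected predictors, moderator mains, the
arm main effect (always included by marginality; coding CT=0, IPT=1), and
moderator×arm interactions. Fivefold cross-validation stratified by arm
yields, for each participant, predictions with arm forced to CT and to
IPT from a model not trained on them. The signed PAI is
`prediction(CT) − prediction(IPT)`: **negative ⇒ CT indicated** (lower
predicted severity is better). Ties at exactly zero are flagged "none" and
excluded from indicated/non-indicated contrasts.

The Johnson–Neyman region for a moderator solves
`δ(m)² = t²_{α/2,df} · SE²(m)` in closed form (quadratic roots), where
`δ(m) = β_arm + Σ_other β_int·mean + β_int·m` and SE comes from the
coefficient covariance; regions are clipped to the observed moderator range
and annotated with the favored arm. Boundaries on the transformed scale are
mapped back to raw units by inverting the fitted transform.

Evaluation contrasts use Student's pooled-variance t (df = n₁+n₂−2,
matching the d = t·√(1/n₁+1/n₂) identity) and Cohen's d with pooled SD:
indicated vs non-indicated on the full sample, within the top-60% |PAI|
subset (⌈0.6·n⌉ kept, boundary ties broken by participant id), and
separately among CT-indicated and IPT-indicated participants. Two PAI score
sets are compared by Pearson correlation of signed scores and a chi-square
(no continuity correction) on the 2×2 recommendation cross-tab.

**Significance of the indicated-vs-non-indicated contrast.** The t-test
comparing observed outcomes of PAI-indicated vs non-indicated participants
is exactly calibrated when the grouping is independent of the outcomes
(simulated type-I rate 5% at n=151). It is *not* calibrated when the
grouping comes out of the pipeline itself: under a null generator (no true
effects anywhere) the primary pipeline rejects at ~33%, because variable
selection on the full sample picks exactly the noise terms that align with
this sample's outcomes; even the nested pipeline rejects at ~12%, because
each participant's group label is a function of the *other* participants'
outcomes through the fold models, which the pooled t-test treats as fixed.
These rates are reported so users read the evaluation p-values as
descriptive, not confirmatory; a calibrated test would need an outer
permutation or data-splitting layer, which the procedure this package
implements does not include.

## Nested validation

`robustness.nested_validate` repeats the whole chain — baseline
residualization, covariate transforms, MOB forest, bootstrap elimination,
final-model fitting — inside each of five training folds (partitioned on a
seed stream independent of the engine's CV), predicting only held-out
participants. Per-fold forests default to 2000 trees (selection runs five
times, so the forest is scaled from the primary run; overridable to
10 000). A leakage audit verifies train/test disjointness and that the test
folds partition the sample. Folds whose selection comes back empty degrade
to an arm-only model and still produce predictions. Imputation precedes
nesting as a data-preparation step.

## Transforms and screening

Pre-selection computes pairwise-complete Pearson correlations corrected for
attenuation (r*_ij = r_ij/√(rel_i·rel_j); reliabilities default to 1.0
since none are stated, configurable per scale; corrected values beyond ±1
are capped with a warning record) and greedily removes the lower-priority
member of the worst pair above |r| = 0.70 until no violations remain.
Priority is an explicit list if given, else mean |correlation| with the
outcome, else list order (the "total scale before subscales" convention).
The judgment call this replaces was a group decision in the original
procedure and is not recoverable; the rule here is a deterministic stand-in.

Transforms: continuous → standardize; counts/discrete/binary → center;
any non-binary variable with |skewness| > 1.0 (a threshold replacing
"visual inspection", configurable) first gets log1p (minimum ≥ 0) or a
shifted square root. Fitted parameters replay exactly on new data. In the
primary mode transforms are fitted on the full sample; nested mode refits
them inside training folds.

## Problem sizes used by the test suite

Oracle tests run at n = 10–200 (closed-form comparisons at 1e-10 to 1e-6
tolerances). Null calibration uses 1000 replicates for the instability test
(n = 200) and 500 full-pipeline replicates under a null generator with
forests of 500 trees and 200 bootstrap resamples. Recovery uses 20 seeded
replicates at n = 151 with 2000-tree forests and 1000 resamples. These
sizes are the package's standard test configuration; the forest scales to
the full 10 000 trees via `MobConfig.n_trees` (used in
`scripts/acceptance.py`).

## Known limitations

- The sup-LM table covers the 2-parameter node model only; other node
  models would need their own simulated table.
- Multi-level unordered categorical split variables are supported in the
  instability test but split search handles binary and ordered variables;
  the default battery contains no multi-level nominals.
- Single imputation only; no between-imputation variance.
- The generator's trajectories are linear in time; trajectory-shape
  misspecification of real data is untested by construction.
- Selection specificity at n≈150 is limited (see stage-2 notes); the
  pipeline reports selection frequencies so users can apply stricter
  thresholds.
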