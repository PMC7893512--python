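# paikit

Personalized Advantage Index (PAI) analysis for two-arm randomized trials
with longitudinal outcomes.

Psychotherapies for depression — here cognitive therapy (CT) and
interpersonal psychotherapy (IPT) — are about equally effective *on
average*, but individuals respond very differently. The PAI approach turns
a trial into a treatment-selection tool: it finds baseline **predictors**
(variables that shift outcomes under both arms) and **moderators**
(variables whose treatment interaction changes which arm is better),
combines them in a moderated regression, and computes for every
participant the cross-validated difference between their predicted outcome
under each arm. The sign of that difference indicates the optimal
treatment; the magnitude, how much it matters.

`paikit` implements the full pipeline for long-term (follow-up) outcomes:

1. **Outcomes** — BDI-II scores at months 7, 8, 9, 10, 11, 12, 24 are
   combined into a natural-cubic-spline area under the curve
   (AUC₇–₂₄, BDI·months), residualized on baseline BDI-II for modelling,
   and divided by the 17-month span for reporting as an average follow-up
   BDI-II.
2. **Imputation** — missing covariates and outcomes are filled by
   iterative random forests (missForest scheme), validated by masking
   complete data and scoring NRMSE / PFC.
3. **Screening** — attenuation-corrected correlations with greedy pruning
   at |r| > 0.70; standardize / center / de-skew transforms.
4. **Stage-1 selection** — a forest of model-based recursive-partitioning
   trees (node model `AUC ~ arm`, score-based parameter-instability tests,
   10 000 trees, split α = 0.10, minimum node 15) ranks variables by
   out-of-bag permutation importance; the threshold is the absolute
   importance of the lowest-ranking variable.
5. **Stage-2 selection** — bootstrap backward elimination (1000 resamples,
   α = 0.05): terms surviving ≥ 60% of resamples are robust; interactions
   make moderators, main effects make predictors.
6. **PAI** — the final model
   `AUC = β₀ + Σβ·predictors + Σβ·moderators + β·arm + Σβ·(moderator×arm)`
   is fitted in fivefold cross-validation (stratified by arm) to produce
   factual and counterfactual predictions; signed PAI =
   prediction(CT) − prediction(IPT), negative ⇒ CT indicated.
   Johnson–Neyman regions locate the moderator values where the
   between-arm difference is significant.
7. **Evaluation** — observed average-BDI of participants randomized to
   their indicated vs non-indicated arm (pooled-variance t, Cohen's d),
   overall, in the top-60% |PAI| subset, and per indicated arm; plus
   agreement between two PAI score sets (correlation, χ²).
8. **Nested validation** — the whole selection chain re-run inside five
   training folds ("no double-dipping"), with a leakage audit.

The original trial data are not publicly deposited, so
`paikit.synthetic_trial` generates trials with the same structure (n=151,
76/75 randomization, 38 mixed-type covariates with correlated blocks, one
planted predictor, two planted count moderators, realistic missingness)
plus the ground truth needed to test recovery. See `docs/methods.md` for
models, parameter defaults, and limitations.

## Worked example

```python
from paikit.synthetic_trial import GeneratorConfig, generate
from paikit.rf_impute import impute_dataset
from paikit.pipeline import PipelineConfig, run_primary
from paikit.mob_forest import MobConfig

data, truth = generate(GeneratorConfig(seed=11))      # 151 participants
data, _ = impute_dataset(data, n_trees=50, seed=3)     # fill missing cells
result = run_primary(
    data,
    PipelineConfig(forest=MobConfig(n_trees=300, seed=5), n_boot=200),
)
print("predictors:", result.predictors)
print("moderators:", result.moderators)
print(result.evaluation_report.text_table())
```

Output (the planted structure is x00 = binary predictor, x01/x02 = count
moderators):

```
predictors: ['x00']
moderators: ['x01', 'x02', 'x30']
contrast                       n1   n2   mean1   mean2      t   df       p      d
indicated_vs_non               72   79    12.4    19.9   5.04  149   0.000   0.82
indicated_vs_non_top           39   52    12.9    20.3   3.52   89   0.001   0.74
ct_indicated                   36   39    14.8    23.6   3.81   73   0.000   0.88
ct_indicated_top               18   29    16.6    23.2   1.98   45   0.053   0.60
ipt_indicated                  36   40    10.1    16.3   3.90   74   0.000   0.90
ipt_indicated_top              21   23     9.7    16.6   3.15   42   0.003   0.95
```

Reading the first row: the 72 participants who were randomized, by chance,
into the arm their PAI indicated ended follow-up 7.5 average-BDI points
lower than the 79 who received the non-indicated arm (d = 0.82, a large
effect because the planted interactions are strong). Both planted
moderators and the planted predictor are recovered; `x30` is a false
positive of the bootstrap-stability rule — the robust set is a shortlist,
not a certificate (see `docs/methods.md`). `result.jn_regions` holds the
Johnson–Neyman intervals: here CT becomes significantly better from about
half a standard deviation above the mean event count upward (roughly two
events on the raw scale) on each planted moderator.

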