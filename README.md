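# eqmap

Mapping EQ-5D-5L index values (health utilities) from routinely
collected data — basic sociodemographics and the three items of the
Minimum European Health Module (MEHM: self-perceived health, chronic
morbidity, activity limitation) — with machine-learning models that are
judged not only on accuracy but on *clinical* accuracy, bias and
fairness.

The package is aimed at outcomes researchers and health economists who
need utility estimates for QALY calculations when direct EQ-5D
measurement is unavailable, and who want to benchmark mapping models
the way a utility-mapping study would: an eight-scenario grid of
predictor sets × missing-data strategies, a clinically grounded metric
suite, rank-based model selection and evolutionary tuning.

## The G goodness metric

Errors smaller than half the minimal clinically important difference
(MCID, 0.066 on the EQ-5D-5L index) are imperceptible, so every raw
error e_i = ŷ_i − y_i is first truncated toward zero by h = MCID/2:

    t_i = sign(e_i) · max(0, |e_i| − h)

From the truncated errors, with E_max = (index range width) − h the
maximum perceivable error (1.848 − 0.033 = 1.815 for a scale anchored
at −0.848 and 1):

    MTAE = mean |t_i|                      (mean truncated absolute error)
    RCA  = 1 − MTAE / E_max                (relative clinical accuracy)
    RCB  = 1 − |mean t_i| / E_max          (relative clinical bias)
    F    = mean over protected variables v of (1 − PPS_v)   (fairness)
    G    = w · RCA · RCB + (1 − w) · F,    w = 0.8 by default

PPS_v is the Predictive Power Score of protected variable v (true
utility, age, sex, education, income, working status) for predicting
the truncated error: cross-validated MAE skill of a shallow regression
tree against a training-fold-median baseline, clipped to [0, 1]. F = 1
means prediction errors carry no information about who the respondent
is.

## What is in the box

| module            | contents |
| ----------------- | -------- |
| `eqmap.valueset`  | EQ-5D-5L health states, additive value-set scoring, MCID/range constants (bundled synthetic illustrative tariff: floor −0.848) |
| `eqmap.synth`     | Gaussian-copula survey generator calibrated to population-sample structure (ceiling effect, predictor–index correlations), MCAR/MAR missingness injection, stratified 60/20/20 splitting |
| `eqmap.impute`    | complete-case deletion, MICE with predictive mean matching (m=30, 10 donors), the eight-scenario grid |
| `eqmap.metrics`   | MSE/RMSE/MAE/R²/r, MTAE, RCA, RCB, PPS, F, G |
| `eqmap.bench`     | 14-learner zoo behind a uniform fit/predict contract, k-fold benchmark tables (min/max/mean/median/std), Friedman-rank model selection, w-sensitivity, overfit checks |
| `eqmap.tune`      | grid search; DE / Nelder-Mead / Powell / COBYLA hyperparameter optimisation; (1+1)EA adaptive elastic-net feature selection |
| `eqmap.report`    | error analysis by index range and demographic group, JSON/CSV reports with run manifests |
| `eqmap.cli`       | `eqmap generate | split | scenario | bench | tune | select-features | report` |

## Worked example

```python
from eqmap.synth import (PopulationConfig, SplitSpec, default_missingness_spec,
                         generate_population, inject_missingness, split_stratified)
from eqmap.impute import ScenarioSpec, build_scenario
from eqmap.bench import run_scenario

pop = generate_population(PopulationConfig(n=2000, seed=7))
table = inject_missingness(pop, default_missingness_spec(), seed=8)
train, val, test = split_stratified(table, SplitSpec(seed=9))

# scenario 2: demographics + MEHM as predictors, missing rows deleted
data = build_scenario(ScenarioSpec(id=2), train, val, test, seed=10)
bench = run_scenario(data, ["LR", "AdaBoost"], folds=5, seed=11)
print(bench.summary.loc[("AdaBoost", "mean"),
                        ["mae", "rmse", "r2", "rca", "rcb", "f", "g"]].round(3))
```

prints

```
mae     0.162
rmse    0.195
r2      0.032
rca     0.928
rcb     0.949
f       0.976
g       0.900
```

Reading: with its stock settings AdaBoost reaches a mean test MAE of
0.162 utility points on this 2,000-respondent synthetic survey; after
MCID truncation its clinical accuracy is RCA 0.928 and its predictions
are nearly unbiased (RCB 0.949) and fair (F 0.976 — errors are nearly
unpredictable from the protected variables), combining to G = 0.900.
The low R² reflects untuned AdaBoost on a heavily ceiling-skewed
index; the study design addresses exactly this with hyperparameter
optimisation (`eqmap.tune`), which prefers few estimators and a square
loss on such data.

The same pipeline runs from the shell:

```sh
eqmap generate --n 2000 --seed 7 --out survey.csv
eqmap split --table survey.csv --seed 9 --out-prefix part
eqmap bench --scenario 2 --split-prefix part --models LR,AdaBoost \
      --folds 5 --seed 11 --out bench_out
```

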