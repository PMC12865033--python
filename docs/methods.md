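# Methods

## Scope and model of the data

`eqmap` implements a utility-mapping study pipeline for population
surveys: respondents answer the EQ-5D-5L (five dimensions, five levels
each) plus the Minimum European Health Module (MEHM) and eight
sociodemographic items; the EQ-5D-5L index `eq5i` is the value-set
score of the five-dimension profile, and the task is to predict `eq5i`
from the other variables. The pipeline covers data generation,
missing-data handling, model benchmarking, model selection, tuning,
feature selection and error analysis.

## Value sets

A value set is represented additively: `index = 1 − Σ decrements`, one
non-negative, level-monotone decrement per (dimension, level), with the
level-1 decrement fixed at zero. This is the form of most published
EQ-5D-5L tariffs. The bundled tariff
(`eqmap/data/value_set_synthetic.csv`) is **synthetic and
illustrative**: it is calibrated only to the anchor points of the
Hungarian scale — index(11111)=1, index(55555)=−0.848, MCID 0.066 — not
to the actual Hungarian coefficients, which are not distributed with
this package. Any real tariff can be supplied as a CSV
(`dimension,level,decrement`) or JSON file; validation enforces
completeness, non-negativity, within-dimension monotonicity and the
full-health anchor.

## The synthetic survey generator

The generator is a Gaussian copula around a single latent health score
`z_h`:

* `(z_age, z_inc, z_h)` are trivariate normal (defaults: corr(age,
  health) −0.32, corr(log-income, health) +0.34, corr(age, income)
  −0.05). Non-positive-definite requests raise a calibration error
  naming the worst pair.
* Age is the inverse-CDF of an eight-group histogram (piecewise-uniform
  within groups, 18–95 years); household income is log-normal (median
  300, log-sd 0.5, in thousand currency units/month).
* Each EQ-5D dimension and each MEHM item is an ordinal cut of
  `λ·(±z_h) + √(1−λ²)·ε` with its own loading λ and marginal category
  probabilities; chronic morbidity is a binary cut at 40% prevalence.
* `eq5i` is computed from the generated profile with the value set,
  never sampled directly, so the generated index is exactly value-set
  consistent record by record.

Coding conventions (the source instruments do not fix numeric
directions, so these are package choices): `sph` 1 best…5 worst,
`gali` 1 severely limited…3 not limited, `chr` 1 = has a long-standing
illness. With these directions the index correlates positively with
`gali` and income and negatively with `sph` and `chr`, matching the
signs the calibration targets.

Defaults were frozen once by moment-matching at n = 50,000
(`scripts/calibrate_generator.py`): loadings (dimensions 0.75, sph
0.71, gali 0.79, chr 0.595) and per-dimension level probabilities
(0.60, 0.21, 0.14, 0.036, 0.014). At n = 20,000 the generated data
shows index–predictor Pearson correlations of about +0.61 (gali),
−0.56 (sph), −0.39 (chr) and +0.23 (income) and ~73% of index values
in [0.75, 1.00] (configured ceiling target 0.70). The index mean
(~0.81) sits a little below what real population samples with the same
ceiling share report (~0.88); hitting all four correlations, the
ceiling share and the mean simultaneously is over-constrained for a
single-factor copula, and the correlations and ceiling were given
priority because the downstream metric behaviour depends on them.

What the generator does **not** emulate: survey-specific quota frames
and census weighting, education/settlement gradients in health,
measurement error in the MEHM, and item-level response styles.
Passing tests on this data show the pipeline's mechanics and
calibrated statistical structure, not performance on any real survey.

## Missingness

Per-variable mechanisms: MCAR with a fixed rate, or MAR with a
logistic nonresponse model in standardised observed driver columns
(intercept solved so the mean probability equals the configured rate).
Defaults average exactly 3% of cells over the 16 non-outcome columns,
with income MAR at 22% driven positively by self-perceived health
(worse health → more nonresponse). The outcome is never made missing;
MAR drivers and the stratification columns (sex, age) are kept fully
observed — the driver constraint is structural (a nonresponse model
cannot condition on a column that is itself blanked by the same spec).

## MICE with predictive mean matching

Each of the m (default 30) imputations runs an independent chain
(sub-seed = seed + chain index): missing cells initialise as random
draws from the observed values; variables are visited in increasing
missingness order (ties by column position) for a fixed number of
sweeps (default 10; reducible for large stacks — the acceptance script
uses 2, which at 3% missingness changes pooled means by far less than
their Monte-Carlo spread); per variable, an OLS linear predictor is fit
on the currently complete data and each missing cell is filled by a
uniform draw among the k = 10 observed values whose linear predictions
are nearest. Imputed cells therefore always hold values observed in
that column, which preserves category domains without explicit
encoding. All variables here are numerically coded, so one linear PMM
engine serves continuous, ordinal and binary columns alike.

The scenario grid crosses predictor sets (odd ids: 8 demographics;
even ids: + 3 MEHM items) with four handling strategies: deletion
(ids 1–2), MICE without the outcome (3–4), MICE using the outcome for
the training split only (5–6), and for training + validation (7–8);
the test split never sees the outcome in its imputation models. Splits
are imputed separately. Models train on the concatenated m×n stack;
evaluation computes metrics per test imputation copy and averages them
(pooling of metrics, not parameters).

## Metrics

Truncation uses signed soft-shrinkage by h = MCID/2 (subtract h from
|e|, keep the sign). The alternative reading — zeroing small errors
but keeping large ones untrimmed — is available as
`strategy="hard_zero"`. Soft-shrinkage is the default because the
reconstructed accuracy rule RCA = 1 − MTAE/(range − h) then reproduces
the published component arithmetic exactly (1 − 0.069/1.815 = 0.962).
E_max defaults to range width − h and is configurable.

PPS uses 4-fold shuffled CV, a depth-4 regression tree, MAE skill
against the training-fold median, clipped at zero; folds and depth are
parameters. A depth-d tree can only recover an identity relationship
up to its 2^d-leaf resolution (skill ≈ 0.94 at depth 4 on a uniform
target), which is the intended behaviour of the published PPS
convention, not an estimation error. Constant targets score 0 by
definition. Fairness targets the *truncated* error, consistent with
the G score being defined on clinically relevant errors throughout.

## Benchmarking and model selection

The 14 model ids are KNN, LoR, LR, PAR, SGD, SVM, DT, MLP, XGBoost,
AdaBoost, CatBoost, LightGBM, DNN, CDNN. All share one contract:
standard-scale features on the training data only, predict, clip to
the index range, deterministic under a seed. Slot notes: LoR is a
logistic-link regression on the min–max rescaled index (a regression
reading of "logistic regression" in a regressor zoo); the CatBoost
slot is served by scikit-learn's histogram gradient boosting
(`HistGradientBoostingRegressor`), the same algorithm family; DNN is a
64×64 feed-forward network; CDNN applies a fixed random 1-D
convolution filter bank (ReLU) over the ordered feature vector ahead
of a small feed-forward head.

Benchmark replicates are the k = 10 cross-validation training portions
of the training split, each evaluated on the fixed test split — the
spread statistics (min/max/mean/median/std) therefore reflect training
-fold variability at a fixed evaluation set. This replicate source is
a package choice (repeated seeded subsampling would be an alternative)
and is the only place the per-model spread originates.

Friedman ranking: within each scenario block, models get midranks of
−G (rank 1 = best); the tie-corrected χ² statistic with k−1 degrees of
freedom tests the null of exchangeable model performance. For n ≤ 5
blocks and k ≤ 4 models an exact permutation p-value over all (k!)^n
within-block orderings is available. The w-sensitivity table recomputes
G over a weight grid (default 0, 0.2, …, 1). Overfit checks report
train−test deltas for G, MAE, R², RMSE with a 0.05 flag threshold on G
and R².

## Tuning and feature selection

`optimize_hyperparams` minimises a user objective (convention: 1 − G
on the validation split) over a mixed space mapped to [0,1]^d —
integers by rounding, categoricals by one-hot relaxation with argmax
decoding — under a hard evaluation budget, with DE (population 15,
rand/1/bin, F = 0.8, CR = 0.9), Nelder-Mead, Powell or COBYLA.
Non-finite objective values reject the candidate.

`aen_select` runs a (1+1)EA over elastic-net configurations: Gaussian
mutations (σ = 0.3) on logit(l1_ratio) and log(alpha), a 0.2-probability
flip of the coordinate-update order, acceptance iff not worse,
stagnation stop after 50 consecutive rejections. The selected features
are the non-zero-coefficient predictors of the incumbent fit. The
comparison objective multiplies the raw validation score by
`1 + 0.02·|subset|`: a one-standard-error-rule analogue. Without it,
selection by realised validation score alone keeps spuriously fitted
noise predictors in roughly half of runs (a fitted noise coefficient
improves the *realised* validation error with probability close to
one half even though it is harmful in expectation); the small
parsimony factor makes a subset earn its size while keeping the
accepted-objective sequence monotone.

## Error analysis

Errors are binned equal-width over [floor, 1] on both the true and the
predicted index (default 10 bins; empty bins reported with count 0).
Group association uses rank tests on absolute errors (Mann-Whitney for
two groups, Kruskal-Wallis beyond) — robust to the skewed error
distribution — with an optional label-permutation p-value (default
10⁴ permutations) as a distribution-free oracle.

## Problem sizes and numerical choices

Tests and the acceptance script run on scaled-down study conditions
chosen as the smallest sizes at which the checked properties are
stable: surveys of 1,000–3,000 respondents for behavioural properties,
20,000 for calibration checks, 9,324 (the survey-database scale the
defaults emulate) for split and stack-size identities, m = 3–5 imputations and 2–5 sweeps
where the full m = 30 is not itself the quantity under test, and 3–5
CV folds in benchmarks. Ties in grid search resolve to the earliest
grid point; stratum splitting uses largest-remainder rounding, with
strata under 3 respondents assigned as a whole by one ratio-weighted
draw; all stochastic components accept explicit seeds and are
reproducible bit-for-bit.

## Known limitations

* The bundled tariff is illustrative; results on it are not Hungarian
  (or any national) utilities.
* The generator's single-factor dependence structure understates the
  mean index for a given ceiling share and carries no
  education/settlement health gradients.
* The CatBoost slot is a different (histogram) gradient-boosting
  implementation; DNN/CDNN are small fixed architectures, not tuned
  deep networks.
* SHAP-based interpretability is not included; the benchmark tables
  and error analysis are the supported model-examination route.
* Friedman blocks are scenarios only (not scenario × fold), so with
  four blocks the test has limited power; the exact permutation option
  exists for exactly this regime.
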