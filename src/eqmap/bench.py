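"""Model zoo, benchmark harness and Friedman-rank model selection.

Fourteen regressor families share a uniform contract: features are
standardised on the training data only, the fitted model predicts one
index value per evaluation row, and predictions are clipped to the value
set's index range.  Model ids:

KNN, LoR, LR, PAR, SGD, SVM, DT, MLP, XGBoost, AdaBoost, CatBoost,
LightGBM, DNN, CDNN.

Notes on individual slots:

* ``LoR`` — the zoo lists logistic regression among regressors; it is
  realised as a logistic-link regression: the index is min-max rescaled
  to (0, 1), logit-transformed, fitted linearly and back-transformed.
* ``CatBoost`` — this slot is served by scikit-learn's
  ``HistGradientBoostingRegressor``, a histogram-based gradient
  boosting machine of the same family.
* ``DNN`` — a small feed-forward network (two 64-unit layers).
* ``CDNN`` — a 1-D convolutional feature map (fixed random filter bank
  with ReLU activation over the ordered feature vector) feeding a small
  feed-forward head.

Benchmark replicates come from k-fold cross-validation on the training
split: each of the ``folds`` models trains on its training portion and
is evaluated on the fixed test split; for imputed test stacks, metrics
are computed per imputation copy and averaged before summarising.  The
best model is selected by the Friedman rank test on mean G over
scenarios (rank 1 = highest G = best).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.ensemble import AdaBoostRegressor, HistGradientBoostingRegressor
from sklearn.linear_model import (
    LinearRegression,
    PassiveAggressiveRegressor,
    SGDRegressor,
)
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .impute import OUTCOME, ScenarioData
from .metrics import (
    DEFAULT_MCID,
    DEFAULT_PROTECTED,
    DEFAULT_RANGE_WIDTH,
    DEFAULT_W,
    g_components,
    g_score,
    metric_panel,
)

__all__ = [
    "MODEL_IDS",
    "make_model",
    "fit_predict",
    "BenchmarkTable",
    "run_scenario",
    "RankTable",
    "friedman_rank",
    "w_sensitivity",
    "overfit_check",
]

MODEL_IDS: tuple[str, ...] = (
    "KNN", "LoR", "LR", "PAR", "SGD", "SVM", "DT", "MLP",
    "XGBoost", "AdaBoost", "CatBoost", "LightGBM", "DNN", "CDNN",
)

#: metrics carried through benchmark tables
_METRIC_KEYS = ("mse", "rmse", "mae", "r2", "pearson_r", "mtae",
                "rca", "rcb", "f", "g")


class LogitLinkRegressor(BaseEstimator, RegressorMixin):
    """Linear regression through a logistic link on a min-max rescaled target.

    The target is rescaled to (eps, 1 - eps) using the training minimum
    and maximum, logit-transformed, fitted by ordinary least squares and
    mapped back through the inverse link.
    """

    def __init__(self, eps: float = 1e-3) -> None:
        self.eps = eps

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        span = max(self.y_max_ - self.y_min_, 1e-12)
        z = np.clip((y - self.y_min_) / span, self.eps, 1 - self.eps)
        self.linear_ = LinearRegression().fit(X, np.log(z / (1 - z)))
        return self

    def predict(self, X):
        from scipy.special import expit

        z = expit(self.linear_.predict(X))
        return self.y_min_ + z * (self.y_max_ - self.y_min_)


class Conv1DFeatureMap(BaseEstimator, TransformerMixin):
    """Fixed random 1-D convolution filter bank over the feature vector.

    Applies ``n_filters`` random kernels of width ``kernel`` along the
    ordered (standardised) feature axis with a ReLU activation; the
    resulting activation map is flattened.  Filters are drawn once at
    fit time from ``seed`` and kept fixed.
    """

    def __init__(self, n_filters: int = 16, kernel: int = 3, seed: int = 0) -> None:
        self.n_filters = n_filters
        self.kernel = kernel
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k = min(self.kernel, X.shape[1])
        rng = np.random.default_rng(self.seed)
        self.filters_ = rng.standard_normal((self.n_filters, k)) / np.sqrt(k)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        k = self.filters_.shape[1]
        windows = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)
        out = np.maximum(np.tensordot(windows, self.filters_, axes=([2], [1])), 0.0)
        return out.reshape(len(X), -1)


def make_model(model_id: str, hyperparams: Mapping | None = None, seed: int = 0):
    """Instantiate one of the fourteen learners with optional overrides."""
    hp = dict(hyperparams or {})
    if model_id == "KNN":
        return KNeighborsRegressor(**{"n_neighbors": 10, **hp})
    if model_id == "LoR":
        return LogitLinkRegressor(**hp)
    if model_id == "LR":
        return LinearRegression(**hp)
    if model_id == "PAR":
        return PassiveAggressiveRegressor(**{"max_iter": 1000, "random_state": seed, **hp})
    if model_id == "SGD":
        return SGDRegressor(**{"random_state": seed, **hp})
    if model_id == "SVM":
        return SVR(**hp)
    if model_id == "DT":
        return DecisionTreeRegressor(**{"random_state": seed, **hp})
    if model_id == "MLP":
        return MLPRegressor(**{"hidden_layer_sizes": (64,), "max_iter": 400,
                               "random_state": seed, **hp})
    if model_id == "XGBoost":
        from xgboost import XGBRegressor

        return XGBRegressor(**{"n_estimators": 200, "max_depth": 4,
                               "random_state": seed, "n_jobs": 1,
                               "verbosity": 0, **hp})
    if model_id == "AdaBoost":
        return AdaBoostRegressor(**{"random_state": seed, **hp})
    if model_id == "CatBoost":
        return HistGradientBoostingRegressor(**{"random_state": seed, **hp})
    if model_id == "LightGBM":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(**{"random_state": seed, "n_jobs": 1,
                                "verbose": -1, **hp})
    if model_id == "DNN":
        return MLPRegressor(**{"hidden_layer_sizes": (64, 64), "max_iter": 400,
                               "random_state": seed, **hp})
    if model_id == "CDNN":
        conv = Conv1DFeatureMap(seed=seed)
        head = MLPRegressor(hidden_layer_sizes=(32,), max_iter=400,
                            random_state=seed, **hp)
        return Pipeline([("conv", conv), ("head", head)])
    raise ValueError(
        f"unknown model id {model_id!r}; supported ids: {', '.join(MODEL_IDS)}"
    )


def fit_predict(
    model: "str | BaseEstimator",
    train: pd.DataFrame,
    eval_data: pd.DataFrame,
    predictors: Sequence[str],
    hyperparams: Mapping | None = None,
    seed: int = 0,
    clip: tuple[float, float] = (1.0 - DEFAULT_RANGE_WIDTH, 1.0),
) -> np.ndarray:
    """Fit one learner and predict the index for every evaluation row.

    Feature standardisation is fitted on the training data only;
    predictions are clipped to the index range.  Deterministic given
    ``seed``.
    """
    est = make_model(model, hyperparams, seed) if isinstance(model, str) else clone(model)
    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    X_tr = train[list(predictors)].to_numpy(dtype=float)
    y_tr = train[OUTCOME].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from iterative fits
        pipe.fit(X_tr, y_tr)
        pred = pipe.predict(eval_data[list(predictors)].to_numpy(dtype=float))
    return np.clip(np.asarray(pred, dtype=float).ravel(), clip[0], clip[1])


@dataclass(frozen=True)
class BenchmarkTable:
    """Per-replicate metric records and their per-model summaries."""

    records: pd.DataFrame   # columns: model, replicate, <metrics>
    summary: pd.DataFrame   # index (model, stat in min/max/mean/median/std)

    def mean_metric(self, model: str, metric: str) -> float:
        return float(self.summary.loc[(model, "mean"), metric])


def _evaluate_predictions(
    test: pd.DataFrame,
    y_pred_by_copy: Mapping[int, np.ndarray],
    protected: Sequence[str],
    mcid: float,
    range_width: float,
    w: float,
    seed: int,
) -> dict[str, float]:
    """Metrics per imputation copy, averaged (plain tables use copy 0)."""
    rows = []
    for imp, part in (
        test.groupby("imp") if "imp" in test.columns else [(0, test)]
    ):
        y_true = part[OUTCOME].to_numpy(dtype=float)
        y_pred = y_pred_by_copy[imp]
        panel = metric_panel(y_true, y_pred, mcid=mcid, range_width=range_width)
        prot_cols = [c for c in protected if c in part.columns or c == OUTCOME]
        prot = pd.DataFrame(
            {c: (y_true if c == OUTCOME else part[c].to_numpy(dtype=float))
             for c in prot_cols}
        )
        comps = g_components(
            y_true, y_pred, prot, mcid=mcid, range_width=range_width,
            w=w, seed=seed,
        )
        rows.append({**panel.to_dict(), "rca": comps.rca, "rcb": comps.rcb,
                     "f": comps.f, "g": comps.g})
    return pd.DataFrame(rows).mean().to_dict()


def run_scenario(
    data: ScenarioData,
    models: Sequence,
    folds: int = 10,
    mcid: float = DEFAULT_MCID,
    w: float = DEFAULT_W,
    protected: Sequence[str] = DEFAULT_PROTECTED,
    seed: int = 0,
    range_width: float = DEFAULT_RANGE_WIDTH,
) -> BenchmarkTable:
    """Benchmark ``models`` on one scenario.

    Replicates are the ``folds`` cross-validation training portions of
    the training split (folds are drawn over respondents, so all
    imputation copies of a respondent stay together); every replicate is
    evaluated on the fixed test split.  ``models`` may mix model-id
    strings and ready estimator objects with fit/predict.
    """
    train, test = data.train, data.test
    if len(train) == 0 or len(test) == 0:
        raise ValueError("scenario has an empty train or test split")
    units = (
        train["rid"].unique() if "rid" in train.columns else train.index.to_numpy()
    )
    if len(units) < folds:
        raise ValueError(f"{len(units)} respondents < {folds} folds")
    predictors = list(data.predictors)
    test_copies = (
        {imp: part for imp, part in test.groupby("imp")}
        if "imp" in test.columns else {0: test}
    )

    records = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for model in models:
        name = model if isinstance(model, str) else type(model).__name__
        if isinstance(model, str) and model not in MODEL_IDS:
            raise ValueError(
                f"unknown model id {model!r}; supported ids: {', '.join(MODEL_IDS)}"
            )
        for rep, (tr_units, _) in enumerate(kf.split(units), start=1):
            unit_set = units[tr_units]
            fold_train = (
                train[train["rid"].isin(unit_set)]
                if "rid" in train.columns else train.iloc[tr_units]
            )
            preds = {
                imp: fit_predict(
                    model, fold_train, part, predictors,
                    seed=seed + rep, clip=(1.0 - range_width, 1.0),
                )
                for imp, part in test_copies.items()
            }
            metrics = _evaluate_predictions(
                test, preds, protected, mcid, range_width, w, seed
            )
            records.append({"model": name, "replicate": rep, **metrics})

    rec = pd.DataFrame(records)
    summary = (
        rec.groupby("model")[list(_METRIC_KEYS)]
        .agg(["min", "max", "mean", "median", "std"])
        .stack(future_stack=True)
    )
    summary.index.names = ["model", "stat"]
    return BenchmarkTable(records=rec, summary=summary)


# ---------------------------------------------------------------------------
# Friedman ranking

@dataclass(frozen=True)
class RankTable:
    """Within-block model ranks and the Friedman test over blocks."""

    ranks: pd.DataFrame        # blocks x models, midranks (1 = best G)
    avg_ranks: pd.Series       # per-model average rank
    chi2: float
    df: int
    p_value: float
    n_blocks: int
    k_treatments: int
    p_exact: float | None = None


def _friedman_chi2(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from a blocks-x-treatments rank matrix."""
    n, k = ranks.shape
    ssbn = float((ranks.sum(axis=0) ** 2).sum())
    chi2 = 12.0 * ssbn / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0  # every block fully tied: no discrimination
    return chi2 / c


def friedman_rank(
    g_means: pd.DataFrame, exact: bool = False
) -> RankTable:
    """Rank models by mean G within each scenario block and test with Friedman.

    ``g_means`` is blocks (scenarios) x treatments (models); higher G
    gets the lower (better) midrank.  ``exact=True`` additionally
    computes the permutation p-value by exhausting all (k!)^n
    within-block orderings (allowed for n <= 5, k <= 4).
    """
    if isinstance(g_means, pd.DataFrame):
        values = g_means.to_numpy(dtype=float)
        cols = list(g_means.columns)
        idx = list(g_means.index)
    else:
        values = np.asarray(g_means, dtype=float)
        cols = [f"model_{j}" for j in range(values.shape[1])]
        idx = [f"block_{i}" for i in range(values.shape[0])]
    if np.isnan(values).any():
        raise ValueError("g_means contains missing cells")
    n, k = values.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 models and 2 blocks")
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in values])
    chi2 = _friedman_chi2(ranks)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    p_exact = None
    if exact:
        if n > 5 or k > 4:
            raise ValueError("exact permutation p restricted to n <= 5, k <= 4")
        base = np.arange(1, k + 1, dtype=float)
        perms = [np.array(p_) for p_ in itertools.permutations(base)]
        stats_null = [
            _friedman_chi2(np.vstack(combo))
            for combo in itertools.product(perms, repeat=n)
        ]
        stats_null = np.array(stats_null)
        p_exact = float(np.mean(stats_null >= chi2 - 1e-12))
    rank_df = pd.DataFrame(ranks, index=idx, columns=cols)
    return RankTable(
        ranks=rank_df,
        avg_ranks=rank_df.mean(axis=0),
        chi2=float(chi2), df=df, p_value=p,
        n_blocks=n, k_treatments=k, p_exact=p_exact,
    )


def w_sensitivity(
    components: pd.DataFrame, weights: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.2), 1))
) -> pd.DataFrame:
    """G per model per importance weight w.

    ``components`` needs columns ``rca``, ``rcb``, ``f`` (one row per
    model).  Returns a models x weights table of G values; the per-w
    rank order can be read off by sorting columns.
    """
    for w in weights:
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {w}")
    out = {}
    for w in weights:
        out[w] = [
            g_score(row["rca"], row["rcb"], row["f"], w)
            for _, row in components.iterrows()
        ]
    return pd.DataFrame(out, index=components.index)


def overfit_check(
    train_metrics: Mapping[str, float],
    test_metrics: Mapping[str, float],
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Train-minus-test deltas for G, MAE, R^2 and RMSE, with overfit flags.

    A metric is flagged when |delta| exceeds its threshold (defaults:
    0.05 for G and R^2; MAE/RMSE reported unflagged unless a threshold
    is supplied).
    """
    thresholds = dict(thresholds or {"g": 0.05, "r2": 0.05})
    rows = []
    for key in ("g", "mae", "r2", "rmse"):
        if key not in train_metrics or key not in test_metrics:
            raise ValueError(f"metric {key!r} missing from train or test metrics")
        delta = float(train_metrics[key]) - float(test_metrics[key])
        thr = thresholds.get(key)
        rows.append({
            "metric": key, "train": float(train_metrics[key]),
            "test": float(test_metrics[key]), "delta": delta,
            "flagged": bool(thr is not None and abs(delta) > thr),
        })
    return pd.DataFrame(rows).set_index("metric")
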