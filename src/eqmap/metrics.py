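"""Clinically grounded performance metrics for utility mapping.

Classical regression metrics are complemented by metrics anchored to the
minimal clinically important difference (MCID) of the EQ-5D-5L index:
prediction errors within +-MCID/2 of the true value are clinically
imperceptible, so every error is first *truncated* — shrunk toward zero
by half the MCID — and the clinically relevant metrics are computed from
the truncated errors ``t_i``:

* MTAE, the mean truncated absolute error;
* RCA = 1 - MTAE / E_max and RCB = 1 - |mean(t)| / E_max, relative
  clinical accuracy and bias, where E_max is the maximum perceivable
  error over the index range (range width minus the half-MCID);
* F, fairness: one minus the mean Predictive Power Score (PPS) of a set
  of protected variables (true utility, age, sex, education, income,
  working status) predicting the truncated error — F = 1 means errors
  carry no signal about who the respondent is;
* the composite goodness score G = w * RCA * RCB + (1 - w) * F with
  importance weight w (default 0.8).

The PPS follows the published convention: k-fold cross-validated MAE
skill of a shallow regression tree on a single feature against a
training-fold-median baseline, clipped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .valueset import DEFAULT_MCID

__all__ = [
    "ErrorVector",
    "MetricPanel",
    "GComponents",
    "truncated_errors",
    "mtae",
    "rca",
    "rcb",
    "pps",
    "fairness",
    "g_score",
    "metric_panel",
    "g_components",
    "DEFAULT_RANGE_WIDTH",
    "DEFAULT_W",
    "DEFAULT_PROTECTED",
]

#: width of the bundled index scale, 1 - (-0.848)
DEFAULT_RANGE_WIDTH: float = 1.848
#: default importance weight of the accuracy/bias product in G
DEFAULT_W: float = 0.8
#: default protected variables for the fairness component; "eq5i" means
#: the true utility itself
DEFAULT_PROTECTED: tuple[str, ...] = ("eq5i", "age", "sex", "edugr", "inc_hh", "work")


def _validate_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size < 1:
        raise ValueError("need at least one pair")
    if not (np.isfinite(yt).all() and np.isfinite(yp).all()):
        raise ValueError("non-finite values in y_true/y_pred")
    return yt, yp


@dataclass(frozen=True)
class ErrorVector:
    """Raw and MCID-truncated prediction errors for one evaluation."""

    y_true: np.ndarray
    y_pred: np.ndarray
    errors: np.ndarray       # e_i = yhat_i - y_i
    truncated: np.ndarray    # t_i = sign(e_i) * max(0, |e_i| - h)
    h: float                 # truncation half-width, MCID / 2

    @property
    def n(self) -> int:
        return self.y_true.size


def truncated_errors(
    y_true, y_pred, mcid: float = DEFAULT_MCID, strategy: str = "soft_shrink"
) -> ErrorVector:
    """Truncate raw errors by the clinically irrelevant half-MCID band.

    ``soft_shrink`` (default) shrinks each error toward zero by
    h = mcid/2, preserving sign; ``hard_zero`` zeroes errors inside the
    band and keeps larger errors untrimmed.
    """
    yt, yp = _validate_pair(y_true, y_pred)
    if not mcid > 0:
        raise ValueError(f"mcid must be > 0, got {mcid}")
    h = mcid / 2.0
    e = yp - yt
    if strategy == "soft_shrink":
        t = np.sign(e) * np.maximum(0.0, np.abs(e) - h)
    elif strategy == "hard_zero":
        t = np.where(np.abs(e) <= h, 0.0, e)
    else:
        raise ValueError(f"unknown truncation strategy {strategy!r}")
    return ErrorVector(y_true=yt, y_pred=yp, errors=e, truncated=t, h=h)


def mtae(ev: ErrorVector) -> float:
    """Mean truncated absolute error."""
    return float(np.mean(np.abs(ev.truncated)))


def _e_max(range_width: float, h: float, mcid: float) -> float:
    if not range_width > mcid:
        raise ValueError(
            f"index range width ({range_width}) must exceed the MCID ({mcid})"
        )
    return range_width - h


def rca(ev: ErrorVector, range_width: float = DEFAULT_RANGE_WIDTH) -> float:
    """Relative clinical accuracy: 1 - MTAE / E_max, clipped to [0, 1]."""
    emax = _e_max(range_width, ev.h, 2 * ev.h)
    return float(np.clip(1.0 - mtae(ev) / emax, 0.0, 1.0))


def rcb(ev: ErrorVector, range_width: float = DEFAULT_RANGE_WIDTH) -> float:
    """Relative clinical bias: 1 - |mean(t_i)| / E_max, clipped to [0, 1]."""
    emax = _e_max(range_width, ev.h, 2 * ev.h)
    return float(np.clip(1.0 - abs(float(np.mean(ev.truncated))) / emax, 0.0, 1.0))


def pps(
    feature,
    target,
    folds: int = 4,
    seed: int = 0,
    max_depth: int = 4,
) -> float:
    """Predictive Power Score of one feature for a continuous target.

    Cross-validated skill of a depth-limited regression tree against a
    training-fold-median baseline, measured by MAE and clipped at zero:
    ``max(0, 1 - MAE_model / MAE_naive)`` averaged over folds.  Detects
    linear and non-linear single-variable relationships; 0 means no
    skill beyond the median, 1 a perfect prediction.
    """
    x = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(target, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("feature and target lengths differ")
    if x.size < 2 * folds:
        raise ValueError(f"need at least {2 * folds} rows for {folds}-fold PPS")
    if np.ptp(y) == 0:
        return 0.0  # constant target: nothing to predict, by definition
    scores = []
    for tr, te in KFold(n_splits=folds, shuffle=True, random_state=seed).split(x):
        tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
        tree.fit(x[tr, None], y[tr])
        mae_model = float(np.mean(np.abs(tree.predict(x[te, None]) - y[te])))
        naive = float(np.median(y[tr]))
        mae_naive = float(np.mean(np.abs(naive - y[te])))
        if mae_naive == 0.0:
            scores.append(0.0)
        else:
            scores.append(max(0.0, 1.0 - mae_model / mae_naive))
    return float(np.mean(scores))


def fairness(
    ev: ErrorVector,
    protected: pd.DataFrame,
    folds: int = 4,
    seed: int = 0,
) -> tuple[float, dict[str, float]]:
    """Fairness F and per-variable PPS values.

    Each protected variable is scored by its PPS for predicting the
    truncated error; F is the mean of the complements (1 - PPS), so 1
    means no association between errors and any protected variable.
    """
    if protected.shape[1] == 0:
        raise ValueError("protected set is empty")
    if len(protected) != ev.n:
        raise ValueError(
            f"protected table has {len(protected)} rows, error vector {ev.n}"
        )
    per_var = {
        str(col): pps(protected[col].to_numpy(dtype=float), ev.truncated,
                      folds=folds, seed=seed)
        for col in protected.columns
    }
    f = float(np.mean([1.0 - v for v in per_var.values()]))
    return f, per_var


def g_score(rca_: float, rcb_: float, f: float, w: float = DEFAULT_W) -> float:
    """Composite goodness: G = w * RCA * RCB + (1 - w) * F."""
    for name, v in (("rca", rca_), ("rcb", rcb_), ("f", f), ("w", w)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float(w * rca_ * rcb_ + (1.0 - w) * f)


@dataclass(frozen=True)
class MetricPanel:
    """Classical metrics plus the MCID-truncated MTAE."""

    mse: float
    rmse: float
    mae: float
    r2: float
    pearson_r: float
    mtae: float

    def to_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse, "rmse": self.rmse, "mae": self.mae,
            "r2": self.r2, "pearson_r": self.pearson_r, "mtae": self.mtae,
        }


def metric_panel(
    y_true,
    y_pred,
    mcid: float = DEFAULT_MCID,
    range_width: float = DEFAULT_RANGE_WIDTH,
) -> MetricPanel:
    """MSE, RMSE, MAE, R^2, Pearson r and MTAE for one prediction vector."""
    yt, yp = _validate_pair(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("need at least two pairs for a metric panel")
    e = yp - yt
    mse = float(np.mean(e**2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("y_true has zero variance; R^2 and r undefined", stacklevel=2)
        r2 = float("nan")
        r = float("nan")
    else:
        r2 = 1.0 - float(np.sum(e**2)) / ss_tot
        sp = float(np.std(yp))
        r = float(np.corrcoef(yt, yp)[0, 1]) if sp > 0 else float("nan")
    ev = truncated_errors(yt, yp, mcid=mcid)
    return MetricPanel(
        mse=mse, rmse=float(np.sqrt(mse)), mae=float(np.mean(np.abs(e))),
        r2=r2, pearson_r=r, mtae=mtae(ev),
    )


@dataclass(frozen=True)
class GComponents:
    """The G score and its components for one prediction vector."""

    rca: float
    rcb: float
    f: float
    w: float
    g: float
    pps_per_variable: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rca": self.rca, "rcb": self.rcb, "f": self.f, "w": self.w,
            "g": self.g, "pps": dict(self.pps_per_variable),
        }


def g_components(
    y_true,
    y_pred,
    protected: pd.DataFrame,
    mcid: float = DEFAULT_MCID,
    range_width: float = DEFAULT_RANGE_WIDTH,
    w: float = DEFAULT_W,
    folds: int = 4,
    seed: int = 0,
) -> GComponents:
    """Compute RCA, RCB, F and G in one call for aligned vectors."""
    ev = truncated_errors(y_true, y_pred, mcid=mcid)
    rca_ = rca(ev, range_width)
    rcb_ = rcb(ev, range_width)
    f, per_var = fairness(ev, protected, folds=folds, seed=seed)
    return GComponents(
        rca=rca_, rcb=rcb_, f=f, w=w,
        g=g_score(rca_, rcb_, f, w), pps_per_variable=per_var,
    )
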