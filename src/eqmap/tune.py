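"""Hyperparameter optimisation and evolutionary elastic-net feature selection.

Two layers of tuning:

* ``grid_search`` exhaustively evaluates a finite grid (first-occurrence
  tie-break);
* ``optimize_hyperparams`` minimises a validation objective over a
  mixed search space with one of four derivative-free methods —
  Differential Evolution (DE), Nelder-Mead (NM), Powell, COBYLA — under
  a hard evaluation budget.  Continuous parameters map to [0, 1]
  coordinates, integers by rounding, categoricals by one-hot relaxation
  decoded to the nearest vertex (argmax).

The default objective convention is minimisation of ``1 - G`` on the
validation split.

``aen_select`` is the adaptive elastic net: a (1+1) evolutionary
algorithm mutates the elastic-net configuration (Gaussian steps on
logit(l1_ratio) and log(alpha), categorical flip of the coordinate
update order), refits, scores the surviving non-zero-coefficient
feature subset on validation, and accepts a mutation iff it is not
worse, until the budget or a stagnation limit is reached.  The score
multiplies the raw validation objective by a small parsimony factor
``1 + parsimony * |subset|`` — a one-standard-error-rule analogue that
stops spuriously fitted noise predictors from surviving on validation
luck alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy.special import expit, logit
from sklearn.linear_model import ElasticNet
from sklearn.preprocessing import StandardScaler

from .metrics import DEFAULT_MCID, DEFAULT_RANGE_WIDTH, DEFAULT_W, g_components

__all__ = [
    "SearchSpace",
    "ADABOOST_SPACE",
    "OptTrace",
    "grid_search",
    "optimize_hyperparams",
    "AENState",
    "AENResult",
    "aen_select",
    "validation_objective",
]

OPT_METHODS = ("DE", "NM", "Powell", "COBYLA")


@dataclass(frozen=True)
class SearchSpace:
    """Mixed hyperparameter domain.

    ``params`` maps a name to ``("float", lo, hi)``, ``("int", lo, hi)``
    or ``("cat", (options...))``.
    """

    params: Mapping[str, tuple]

    def __post_init__(self) -> None:
        for name, spec in self.params.items():
            kind = spec[0]
            if kind in ("float", "int"):
                if not spec[1] < spec[2]:
                    raise ValueError(f"empty interval for {name!r}: {spec}")
            elif kind == "cat":
                if len(spec[1]) == 0:
                    raise ValueError(f"empty categorical set for {name!r}")
            else:
                raise ValueError(f"unknown domain kind {kind!r} for {name!r}")

    @property
    def dim(self) -> int:
        return sum(
            len(s[1]) if s[0] == "cat" else 1 for s in self.params.values()
        )

    def decode(self, x: np.ndarray) -> dict:
        """Map a [0, 1]^dim vector to a concrete parameter dict."""
        out: dict = {}
        i = 0
        for name, spec in self.params.items():
            if spec[0] == "float":
                out[name] = float(spec[1] + np.clip(x[i], 0, 1) * (spec[2] - spec[1]))
                i += 1
            elif spec[0] == "int":
                out[name] = int(round(spec[1] + np.clip(x[i], 0, 1) * (spec[2] - spec[1])))
                i += 1
            else:
                opts = spec[1]
                j = int(np.argmax(x[i : i + len(opts)]))
                out[name] = opts[j]
                i += len(opts)
        return out


#: default AdaBoost search space
ADABOOST_SPACE = SearchSpace({
    "learning_rate": ("float", 0.01, 2.0),
    "n_estimators": ("int", 2, 200),
    "loss": ("cat", ("linear", "square", "exponential")),
})


@dataclass
class OptTrace:
    """Evaluation log of one optimisation run."""

    method: str
    budget: int
    seed: int
    records: list = field(default_factory=list)

    def log(self, params: Mapping, value: float) -> None:
        best = min(self.best, value) if self.records else value
        self.records.append({"iteration": len(self.records) + 1,
                             **params, "objective": value, "best": best})

    @property
    def best(self) -> float:
        return self.records[-1]["best"] if self.records else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def grid_search(
    objective: Callable[[Mapping], float],
    grid: Mapping[str, Sequence],
) -> tuple[dict, pd.DataFrame]:
    """Evaluate every grid point once; return the argmin and the table.

    Ties are broken by first occurrence in grid order (and logged).
    """
    names = list(grid.keys())
    points = list(product(*[grid[n] for n in names]))
    if not points:
        raise ValueError("empty grid")
    rows = []
    best_val, best_params = float("inf"), None
    for values in points:
        params = dict(zip(names, values))
        val = float(objective(params))
        rows.append({**params, "objective": val})
        if val < best_val - 1e-15:
            best_val, best_params = val, params
        elif best_params is not None and val <= best_val + 1e-15:
            warnings.warn(
                f"grid tie at objective {val}: keeping earlier point "
                f"{best_params}", stacklevel=2,
            )
    return best_params, pd.DataFrame(rows)


class _BudgetExhausted(Exception):
    pass


def optimize_hyperparams(
    objective: Callable[[Mapping], float],
    space: SearchSpace,
    method: str = "DE",
    budget: int = 200,
    seed: int = 0,
) -> tuple[dict, OptTrace]:
    """Minimise ``objective`` over ``space`` with a derivative-free method.

    ``objective`` receives a decoded parameter dict and returns a float;
    non-finite returns reject the candidate.  At most ``budget``
    objective evaluations are spent; the best decoded candidate and the
    full trace are returned.
    """
    if method not in OPT_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {OPT_METHODS}")
    if budget < 10:
        raise ValueError("budget must be at least 10")
    trace = OptTrace(method=method, budget=budget, seed=seed)
    rng = np.random.default_rng(seed)
    best = {"x": None, "val": float("inf")}

    def wrapped(x: np.ndarray) -> float:
        if len(trace.records) >= budget:
            raise _BudgetExhausted
        params = space.decode(np.asarray(x, dtype=float))
        val = float(objective(params))
        if not np.isfinite(val):
            warnings.warn(f"non-finite objective at {params}; rejected", stacklevel=2)
            val = 1e12
        trace.log(params, val)
        if val < best["val"]:
            best["val"], best["x"] = val, np.asarray(x, dtype=float).copy()
        return val

    d = space.dim
    bounds = [(0.0, 1.0)] * d
    try:
        if method == "DE":
            sciopt.differential_evolution(
                wrapped, bounds, seed=seed, popsize=15, strategy="rand1bin",
                mutation=0.8, recombination=0.9, polish=False, tol=0,
                maxiter=max(1, budget // (15 * d) + 1),
            )
        else:
            x0 = rng.random(d)
            scipy_name = {"NM": "Nelder-Mead", "Powell": "Powell",
                          "COBYLA": "COBYLA"}[method]
            options = ({"maxiter": budget * 4} if method == "COBYLA"
                       else {"maxiter": budget * 4, "maxfev": budget * 4})
            sciopt.minimize(
                wrapped, x0, method=scipy_name, bounds=bounds, options=options,
            )
    except _BudgetExhausted:
        pass
    if best["x"] is None:  # pragma: no cover - budget >= 10 guarantees evals
        raise RuntimeError("optimizer performed no evaluations")
    return space.decode(best["x"]), trace


# ---------------------------------------------------------------------------
# adaptive elastic net feature selection

@dataclass(frozen=True)
class AENState:
    """One elastic-net configuration visited by the (1+1)EA."""

    l1_ratio: float
    alpha: float
    selection: str
    objective: float          # parsimony-penalised validation objective
    raw_objective: float      # validation objective before the penalty
    subset: tuple[str, ...]


@dataclass(frozen=True)
class AENResult:
    selected: tuple[str, ...]
    best_state: AENState
    trace: pd.DataFrame


def validation_objective(
    y_val: np.ndarray,
    y_pred: np.ndarray,
    protected: pd.DataFrame | None = None,
    w: float = DEFAULT_W,
    mcid: float = DEFAULT_MCID,
    range_width: float = DEFAULT_RANGE_WIDTH,
    seed: int = 0,
) -> float:
    """1 - G when a protected table is available, validation MAE otherwise."""
    if protected is not None:
        comp = g_components(
            y_val, y_pred, protected, mcid=mcid, range_width=range_width,
            w=w, seed=seed,
        )
        return 1.0 - comp.g
    return float(np.mean(np.abs(np.asarray(y_pred) - np.asarray(y_val))))


def aen_select(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    budget: int = 100,
    seed: int = 0,
    protected: pd.DataFrame | None = None,
    sigma: float = 0.3,
    flip_prob: float = 0.2,
    stagnation: int = 50,
    w: float = DEFAULT_W,
    parsimony: float = 0.02,
) -> AENResult:
    """(1+1)EA over elastic-net configurations; returns the selected subset.

    Each iteration mutates the incumbent (Gaussian steps of size
    ``sigma`` on logit(l1_ratio) and log(alpha); coordinate-update order
    flipped with probability ``flip_prob``), refits the elastic net on
    standardised training data, and scores predictions on the
    validation split; the mutation is accepted iff not worse.  The
    comparison uses the raw validation objective inflated by
    ``1 + parsimony * |subset|``, so a subset must earn its size on
    validation.  Stops after ``budget`` evaluations or ``stagnation``
    consecutive rejections.  Deterministic given (data, budget, seed).
    """
    if budget < 20:
        raise ValueError("budget must be at least 20")
    cols = list(X_train.columns)
    Xt = np.asarray(X_train, dtype=float)
    Xv = np.asarray(X_val, dtype=float)
    yt = np.asarray(y_train, dtype=float)
    yv = np.asarray(y_val, dtype=float)
    if np.all(Xt.std(axis=0) == 0):
        raise ValueError("all predictors are constant")
    scaler = StandardScaler().fit(Xt)
    Xt_s, Xv_s = scaler.transform(Xt), scaler.transform(Xv)
    rng = np.random.default_rng(seed)
    selections = ("cyclic", "random")

    def evaluate(l1_ratio: float, alpha: float, selection: str) -> AENState | None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = ElasticNet(
                    alpha=alpha, l1_ratio=l1_ratio, selection=selection,
                    random_state=seed, max_iter=5000,
                ).fit(Xt_s, yt)
        except Exception as exc:  # fit failure: mutation rejected
            warnings.warn(f"elastic-net fit failed ({exc}); mutation rejected",
                          stacklevel=2)
            return None
        subset = tuple(c for c, b in zip(cols, net.coef_) if abs(b) > 1e-8)
        raw = validation_objective(
            yv, net.predict(Xv_s), protected=protected, w=w, seed=seed
        )
        obj = float(raw) * (1.0 + parsimony * len(subset))
        return AENState(l1_ratio=l1_ratio, alpha=alpha, selection=selection,
                        objective=obj, raw_objective=float(raw), subset=subset)

    incumbent = evaluate(0.5, 0.05, "cyclic")
    if incumbent is None:
        raise ValueError("initial elastic-net fit failed")
    rows = [{"iteration": 0, "l1_ratio": incumbent.l1_ratio,
             "alpha": incumbent.alpha, "selection": incumbent.selection,
             "objective": incumbent.objective,
             "raw_objective": incumbent.raw_objective, "accepted": True,
             "n_selected": len(incumbent.subset)}]
    rejected_streak = 0
    for it in range(1, budget):
        if rejected_streak >= stagnation:
            break
        l1 = float(expit(logit(np.clip(incumbent.l1_ratio, 1e-6, 1 - 1e-6))
                         + sigma * rng.standard_normal()))
        alpha = float(np.exp(np.log(incumbent.alpha) + sigma * rng.standard_normal()))
        sel = incumbent.selection
        if rng.random() < flip_prob:
            sel = selections[1 - selections.index(sel)]
        cand = evaluate(l1, alpha, sel)
        accepted = cand is not None and cand.objective <= incumbent.objective
        if accepted:
            incumbent = cand
            rejected_streak = 0
        else:
            rejected_streak += 1
        rows.append({
            "iteration": it,
            "l1_ratio": l1, "alpha": alpha, "selection": sel,
            "objective": cand.objective if cand is not None else float("nan"),
            "raw_objective": cand.raw_objective if cand is not None else float("nan"),
            "accepted": accepted,
            "n_selected": len(cand.subset) if cand is not None else 0,
        })
    return AENResult(
        selected=incumbent.subset, best_state=incumbent,
        trace=pd.DataFrame(rows),
    )
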