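"""Missing-data handling: deletion, MICE with predictive mean matching,
and the eight predictor-set x handling scenario grid.

Four strategies are compared in the study design:

* ``DELETE`` — complete-case analysis;
* ``MICE_NO_Y`` — multiple imputation by chained equations with
  predictive mean matching (PMM), the outcome excluded from every
  imputation model;
* ``MICE_Y_TRAIN`` — the outcome used in the imputation models of the
  training split only;
* ``MICE_Y_TRAIN_VAL`` — the outcome used for training and validation
  splits, never for the test split.

Scenario ids 1..8 cross the two predictor sets (odd ids: demographics
only; even ids: demographics + MEHM) with the four strategies in the
order above.  Each split is imputed separately.

The MICE-PMM engine fits, per variable with missing cells, an ordinary
linear predictor on the currently complete data, and fills each missing
cell with the observed value of one of the ``k`` donors whose linear
predictions are nearest — so imputed values are always values actually
observed in that column (category preserving).  ``m`` chains run with
independent sub-seeds (``seed + imputation index``) and are returned
stacked with an ``imp`` tag 1..m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DEMO_PREDICTORS",
    "MEHM_PREDICTORS",
    "OUTCOME",
    "ScenarioSpec",
    "ScenarioData",
    "delete_incomplete",
    "MICEPMMImputer",
    "mice_pmm",
    "build_scenario",
]

DEMO_PREDICTORS: tuple[str, ...] = (
    "sex", "age", "edugr", "stype", "fam", "work", "hhn", "inc_hh",
)
MEHM_PREDICTORS: tuple[str, ...] = ("sph", "chr", "gali")
OUTCOME = "eq5i"

_HANDLINGS = ("DELETE", "MICE_NO_Y", "MICE_Y_TRAIN", "MICE_Y_TRAIN_VAL")


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the eight predictor-set x missing-data-handling scenarios."""

    id: int
    m: int = 30
    k_donors: int = 10
    sweeps: int = 10

    def __post_init__(self) -> None:
        if self.id not in range(1, 9):
            raise ValueError(f"scenario id must be 1..8, got {self.id}")

    @property
    def predictor_set(self) -> str:
        return "DEMO" if self.id % 2 == 1 else "DEMO_MEHM"

    @property
    def predictors(self) -> tuple[str, ...]:
        demo = DEMO_PREDICTORS
        return demo if self.id % 2 == 1 else demo + MEHM_PREDICTORS

    @property
    def handling(self) -> str:
        return _HANDLINGS[(self.id - 1) // 2]


@dataclass(frozen=True)
class ScenarioData:
    """Scenario-ready train/validation/test data.

    Under ``DELETE`` each part is a plain complete-case table; under the
    MICE handlings each part is an imputed stack with an ``imp`` column
    tagging the imputation copy 1..m.
    """

    spec: ScenarioSpec
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    predictors: tuple[str, ...] = field(default=())

    @property
    def is_stacked(self) -> bool:
        return "imp" in self.train.columns


def delete_incomplete(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Complete-case filter: keep rows without missing cells, order kept."""
    cols = list(columns) if columns is not None else list(table.columns)
    out = table[table[cols].notna().all(axis=1)]
    if len(out) == 0:
        raise ValueError("no complete rows remain after deletion")
    return out.copy()


class MICEPMMImputer(BaseEstimator, TransformerMixin):
    """Chained-equation multiple imputation with predictive mean matching.

    Parameters
    ----------
    m : number of imputations (stacked copies returned).
    k_donors : donor pool size for PMM.
    sweeps : chained-equation cycles per imputation.
    include_outcome : whether the ``outcome`` column enters the
        per-variable imputation models as a predictor.
    outcome : name of the outcome column (never imputed here; the
        generator guarantees it complete).
    id_column : respondent identifier carried through but not modelled.
    seed : base seed; chain ``i`` uses ``seed + i``.
    """

    def __init__(
        self,
        m: int = 30,
        k_donors: int = 10,
        sweeps: int = 10,
        include_outcome: bool = False,
        outcome: str = OUTCOME,
        id_column: str = "rid",
        seed: int = 0,
    ) -> None:
        self.m = m
        self.k_donors = k_donors
        self.sweeps = sweeps
        self.include_outcome = include_outcome
        self.outcome = outcome
        self.id_column = id_column
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "MICEPMMImputer":
        model_cols = [
            c for c in X.columns if c != self.id_column
            and (self.include_outcome or c != self.outcome)
        ]
        if len(model_cols) < 2:
            raise ValueError("need at least two columns to chain imputations")
        for c in model_cols:
            if not pd.api.types.is_numeric_dtype(X[c]):
                raise ValueError(
                    f"column {c!r} is not numeric; encode categories first"
                )
            n_obs = int(X[c].notna().sum())
            if X[c].isna().any() and n_obs < self.k_donors:
                raise ValueError(
                    f"variable {c!r} has only {n_obs} observed values; "
                    f"PMM needs at least k_donors = {self.k_donors}"
                )
        self.model_columns_ = model_cols
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the m completed copies stacked, tagged by ``imp`` = 1..m."""
        if not hasattr(self, "model_columns_"):
            self.fit(X)
        cols = self.model_columns_
        mat = X[cols].to_numpy(dtype=float)
        miss = np.isnan(mat)
        copies = []
        for i in range(1, self.m + 1):
            filled = X.copy()
            if miss.any():
                imputed = self._impute_once(mat, miss, np.random.default_rng(self.seed + i))
                for j, c in enumerate(cols):
                    filled[c] = imputed[:, j]
            filled.insert(0, "imp", i)
            copies.append(filled)
        return pd.concat(copies, ignore_index=True)

    fit_transform = TransformerMixin.fit_transform

    # -- one chain ---------------------------------------------------------

    def _impute_once(
        self, mat: np.ndarray, miss: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        cur = mat.copy()
        n, p = cur.shape
        # initialise missing cells by random draws from observed values
        for j in range(p):
            mj = miss[:, j]
            if mj.any():
                obs = cur[~mj, j]
                cur[mj, j] = rng.choice(obs, size=int(mj.sum()), replace=True)
        # visit variables in increasing-missingness order, ties by position
        frac = miss.mean(axis=0)
        visit = [j for j in np.lexsort((np.arange(p), frac)) if frac[j] > 0]
        for _ in range(self.sweeps):
            for j in visit:
                mj = miss[:, j]
                others = [k for k in range(p) if k != j]
                design = np.column_stack([np.ones(n), cur[:, others]])
                beta, *_ = np.linalg.lstsq(design[~mj], mat[~mj, j], rcond=None)
                pred = design @ beta
                cur[mj, j] = self._pmm_draw(
                    pred_obs=pred[~mj], y_obs=mat[~mj, j], pred_mis=pred[mj], rng=rng
                )
        return cur

    def _pmm_draw(
        self,
        pred_obs: np.ndarray,
        y_obs: np.ndarray,
        pred_mis: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Uniform draw among the k observed values nearest in prediction."""
        k = min(self.k_donors, pred_obs.size)
        order = np.argsort(pred_obs, kind="stable")
        sp, sy = pred_obs[order], y_obs[order]
        pos = np.searchsorted(sp, pred_mis)
        # a window of 2k candidates around the insertion point always
        # contains the k nearest predictions
        offs = np.arange(-k, k)
        win = np.clip(pos[:, None] + offs[None, :], 0, sp.size - 1)
        diffs = np.abs(sp[win] - pred_mis[:, None])
        nearest = np.argpartition(diffs, k - 1, axis=1)[:, :k]
        pick = rng.integers(0, k, size=pred_mis.size)
        donor_idx = np.take_along_axis(win, nearest, axis=1)[
            np.arange(pred_mis.size), pick
        ]
        return sy[donor_idx]


def mice_pmm(
    table: pd.DataFrame,
    m: int = 30,
    k_donors: int = 10,
    include_outcome: bool = False,
    seed: int = 0,
    sweeps: int = 10,
) -> pd.DataFrame:
    """Impute ``table`` m times with MICE-PMM; returns the stacked copies."""
    imp = MICEPMMImputer(
        m=m, k_donors=k_donors, sweeps=sweeps,
        include_outcome=include_outcome, seed=seed,
    )
    return imp.fit_transform(table)


def build_scenario(
    spec: ScenarioSpec,
    train: pd.DataFrame,
    val: pd.DataFrame,
    test: pd.DataFrame,
    seed: int = 0,
) -> ScenarioData:
    """Apply the scenario's predictor restriction and missing-data handling.

    The three splits are processed separately; for the MICE handlings
    the outcome enters the imputation models of a split exactly when the
    scenario prescribes it (never for the test split).
    """
    keep = [c for c in ("rid",) if c in train.columns]
    cols = keep + list(spec.predictors) + [OUTCOME]
    parts = []
    for name, part in (("train", train), ("val", val), ("test", test)):
        missing = [c for c in cols if c not in part.columns]
        if missing:
            raise ValueError(f"{name} split lacks columns {missing}")
        parts.append(part[cols])
    tr, va, te = parts

    if spec.handling == "DELETE":
        return ScenarioData(
            spec=spec,
            train=delete_incomplete(tr),
            val=delete_incomplete(va),
            test=delete_incomplete(te),
            predictors=spec.predictors,
        )

    use_y = {
        "MICE_NO_Y": (False, False, False),
        "MICE_Y_TRAIN": (True, False, False),
        "MICE_Y_TRAIN_VAL": (True, True, False),
    }[spec.handling]
    out = []
    for offset, (part, incl) in enumerate(zip((tr, va, te), use_y)):
        imputer = MICEPMMImputer(
            m=spec.m, k_donors=spec.k_donors, sweeps=spec.sweeps,
            include_outcome=incl, seed=seed + 1000 * offset,
        )
        out.append(imputer.fit_transform(part))
    return ScenarioData(
        spec=spec, train=out[0], val=out[1], test=out[2],
        predictors=spec.predictors,
    )
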