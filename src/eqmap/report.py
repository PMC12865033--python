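"""Error analysis by index range and demographic group, and report output.

Prediction error in utility mapping is typically not uniform over the
index scale: errors grow and become positively biased toward poor
health states, because population samples are dominated by respondents
near full health.  ``error_analysis`` quantifies this by binning errors
over the index range (on both the true and the predicted index) and by
testing the association of absolute errors with demographic groups
using rank tests (Mann-Whitney/Kruskal-Wallis) with an optional
label-permutation oracle.

``write_report`` serialises run artifacts as a machine-readable JSON
report plus CSV tables, together with a run manifest (configuration,
seeds, package versions) so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorReport",
    "error_analysis",
    "group_rank_test",
    "write_report",
    "validate_report",
    "run_manifest",
]


@dataclass(frozen=True)
class ErrorReport:
    """Binned error profile plus per-group association tests."""

    bin_edges: np.ndarray
    by_true_bin: pd.DataFrame
    by_pred_bin: pd.DataFrame
    group_tests: pd.DataFrame
    n: int


def _bin_summary(y_ref: np.ndarray, errors: np.ndarray, edges: np.ndarray) -> pd.DataFrame:
    idx = np.clip(np.digitize(y_ref, edges[1:-1], right=False), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        count = int(sel.sum())
        rows.append({
            "bin": b, "lo": float(edges[b]), "hi": float(edges[b + 1]),
            "count": count,
            "mean_error": float(errors[sel].mean()) if count else float("nan"),
            "mean_abs_error": float(np.abs(errors[sel]).mean()) if count else float("nan"),
        })
    return pd.DataFrame(rows)


def group_rank_test(
    abs_errors: np.ndarray,
    groups: np.ndarray,
    permutations: int = 0,
    seed: int = 0,
) -> tuple[float, float, float | None]:
    """Rank-based association of absolute errors with group membership.

    Two groups use the Mann-Whitney U test, more use its k-group
    extension (Kruskal-Wallis).  With ``permutations`` > 0 a
    label-permutation p-value of the Kruskal-Wallis H statistic is also
    returned as a distribution-free oracle.
    """
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [abs_errors[groups == g] for g in labels]
    if len(labels) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    else:
        stat, p = stats.kruskal(*samples)
    p_perm = None
    if permutations > 0:
        h_obs = stats.kruskal(*samples).statistic
        rng = np.random.default_rng(seed)
        ranks = stats.rankdata(abs_errors)
        n = len(abs_errors)
        sizes = np.array([len(s) for s in samples])
        exceed = 0
        for _ in range(permutations):
            perm = rng.permutation(ranks)
            start, ss = 0, 0.0
            for sz in sizes:
                r = perm[start:start + sz]
                ss += r.sum() ** 2 / sz
                start += sz
            h = 12.0 / (n * (n + 1)) * ss - 3 * (n + 1)
            if h >= h_obs - 1e-12:
                exceed += 1
        p_perm = (exceed + 1) / (permutations + 1)
    return float(stat), float(p), p_perm


def error_analysis(
    y_true,
    y_pred,
    groups: pd.DataFrame | None = None,
    bins: int = 10,
    floor: float = -0.848,
    permutations: int = 0,
    seed: int = 0,
) -> ErrorReport:
    """Bin prediction errors over the index range and test group association.

    Bins are equal-width over [floor, 1] and computed on both the true
    and the predicted index; empty bins are reported with count 0 and
    no statistics.
    """
    if bins < 3:
        raise ValueError("need at least 3 bins")
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    errors = yp - yt
    edges = np.linspace(floor, 1.0, bins + 1)
    tests = []
    if groups is not None:
        if len(groups) != len(yt):
            raise ValueError("groups table not aligned with predictions")
        for col in groups.columns:
            if groups[col].isna().any():
                raise ValueError(f"group column {col!r} contains missing values")
            stat, p, p_perm = group_rank_test(
                np.abs(errors), groups[col].to_numpy(),
                permutations=permutations, seed=seed,
            )
            tests.append({"group": col, "statistic": stat, "p_value": p,
                          "p_permutation": p_perm})
    return ErrorReport(
        bin_edges=edges,
        by_true_bin=_bin_summary(yt, errors, edges),
        by_pred_bin=_bin_summary(yp, errors, edges),
        group_tests=pd.DataFrame(
            tests, columns=["group", "statistic", "p_value", "p_permutation"]
        ),
        n=len(yt),
    )


# ---------------------------------------------------------------------------
# serialisation

#: keys every metrics block of a report must provide
METRIC_KEYS = ("mse", "rmse", "mae", "r2", "pearson_r", "mtae",
               "rca", "rcb", "f", "w", "g", "pps")


def run_manifest(config: Mapping | None = None, seed: int | None = None) -> dict:
    """Reproducibility manifest: configuration, seed and package versions."""
    import sklearn

    import eqmap

    return {
        "config": dict(config or {}),
        "seed": seed,
        "python": platform.python_version(),
        "versions": {
            "eqmap": eqmap.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def validate_report(report: Mapping) -> None:
    """Check a report object against the shipped schema (raises on failure)."""
    for key in ("manifest", "metrics"):
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for block_name, block in report["metrics"].items():
        missing = [k for k in METRIC_KEYS if k not in block]
        if missing:
            raise ValueError(
                f"metrics block {block_name!r} missing keys {missing}"
            )


def write_report(
    destination: "str | Path",
    metrics: Mapping[str, Mapping],
    tables: Mapping[str, pd.DataFrame] | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
    error_report: ErrorReport | None = None,
) -> dict:
    """Write the JSON report plus CSV tables under ``destination``.

    ``metrics`` maps block names (e.g. scenario/model labels) to metric
    dicts containing every key in ``METRIC_KEYS``.  Returns the report
    object that was written.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    report = {
        "manifest": run_manifest(config=config, seed=seed),
        "metrics": {k: dict(v) for k, v in metrics.items()},
    }
    if error_report is not None:
        report["error_analysis"] = {
            "n": error_report.n,
            "bin_edges": [float(x) for x in error_report.bin_edges],
            "group_tests": error_report.group_tests.to_dict(orient="records"),
        }
    validate_report(report)
    with open(dest / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    for name, frame in (tables or {}).items():
        frame.to_csv(dest / f"{name}.csv", index=True)
    if error_report is not None:
        error_report.by_true_bin.to_csv(dest / "errors_by_true_bin.csv", index=False)
        error_report.by_pred_bin.to_csv(dest / "errors_by_pred_bin.csv", index=False)
    return report
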