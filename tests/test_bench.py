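"""Model zoo contract, benchmark harness, Friedman ranking, overfit check."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqmap.bench import (
    MODEL_IDS,
    fit_predict,
    friedman_rank,
    make_model,
    overfit_check,
    run_scenario,
    w_sensitivity,
)
from eqmap.impute import ScenarioData, ScenarioSpec, build_scenario
from eqmap.metrics import g_components, metric_panel


def _linear_frame(n, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, (n, 3))
    y = 0.3 * X[:, 0] - 0.2 * X[:, 1] + 0.1 * X[:, 2] + 0.5
    y = np.clip(y + noise * rng.standard_normal(n), -0.848, 1.0)
    frame = pd.DataFrame(X, columns=["a", "b", "c"])
    frame["eq5i"] = y
    return frame


def test_linear_model_recovers_noiseless_signal():
    train, test = _linear_frame(300, 1), _linear_frame(100, 2)
    pred = fit_predict("LR", train, test, ["a", "b", "c"], seed=0)
    assert metric_panel(test.eq5i, pred).r2 >= 0.999


def test_unknown_model_id_lists_supported():
    with pytest.raises(ValueError, match="RandomForest.*KNN.*CDNN"):
        make_model("RandomForest")
    assert len(MODEL_IDS) == 14


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_every_model_fits_and_predicts_deterministically(model_id):
    train, test = _linear_frame(120, 3, noise=0.05), _linear_frame(40, 4, noise=0.05)
    p1 = fit_predict(model_id, train, test, ["a", "b", "c"], seed=5)
    p2 = fit_predict(model_id, train, test, ["a", "b", "c"], seed=5)
    np.testing.assert_array_equal(p1, p2)
    assert p1.shape == (40,)
    assert (p1 >= -0.848).all() and (p1 <= 1.0).all()


def _tiny_scenario(seed=0, oracle=False):
    """A DELETE-style scenario whose outcome is a noisy (or exact) linear
    function of the predictors; with ``oracle`` one predictor equals the
    outcome so a linear fit becomes a perfect predictor."""
    rng = np.random.default_rng(seed)
    parts = []
    for n in (400, 100, 150):
        frame = _linear_frame(n, seed + n, noise=0.0 if oracle else 0.08)
        if oracle:
            frame["a"] = frame["eq5i"]
        frame.insert(0, "rid", np.arange(n))
        parts.append(frame)
    spec = ScenarioSpec(id=1)
    return ScenarioData(spec=spec, train=parts[0], val=parts[1],
                        test=parts[2], predictors=("a", "b", "c"))


def test_oracle_predictor_scores_perfect_g():
    data = _tiny_scenario(seed=1, oracle=True)
    table = run_scenario(data, ["LR"], folds=3, protected=("a", "b"), seed=2)
    means = table.records.groupby("model").mean()
    assert means.loc["LR", "mae"] == pytest.approx(0.0, abs=1e-9)
    assert means.loc["LR", "g"] == pytest.approx(1.0, abs=1e-6)


def test_summary_exposes_exactly_the_five_statistics():
    data = _tiny_scenario(seed=3)
    table = run_scenario(data, ["LR", "DT"], folds=3, protected=("a",), seed=4)
    stats_seen = set(table.summary.index.get_level_values("stat"))
    assert stats_seen == {"min", "max", "mean", "median", "std"}
    assert set(table.summary.index.get_level_values("model")) == {"LR", "DT"}
    for metric in ("rmse", "mae", "g"):
        col = table.summary[metric].unstack()
        assert (col["min"] <= col["median"] + 1e-12).all()
        assert (col["median"] <= col["max"] + 1e-12).all()
        assert col["mean"].between(col["min"] - 1e-12, col["max"] + 1e-12).all()


def test_run_scenario_deterministic():
    data = _tiny_scenario(seed=5)
    t1 = run_scenario(data, ["DT"], folds=3, protected=("a",), seed=6)
    t2 = run_scenario(data, ["DT"], folds=3, protected=("a",), seed=6)
    pd.testing.assert_frame_equal(t1.records, t2.records)


def test_imputed_test_stack_metrics_are_averaged(survey_splits):
    tr, va, te = survey_splits
    data = build_scenario(ScenarioSpec(id=4, m=2, sweeps=2), tr, va, te, seed=7)
    table = run_scenario(data, ["LR"], folds=3, seed=8)
    assert len(table.records) == 3
    assert table.records.g.between(0, 1).all()


# -- Friedman ---------------------------------------------------------------

def test_identical_ranks_fixture_gives_chi2_eight():
    g = pd.DataFrame(
        [[0.9, 0.8, 0.7]] * 4, columns=["m1", "m2", "m3"]
    )
    rt = friedman_rank(g)
    assert rt.chi2 == pytest.approx(8.0, abs=1e-12)
    assert rt.df == 2
    assert rt.avg_ranks.tolist() == [1.0, 2.0, 3.0]


def test_full_ties_give_zero_statistic():
    g = pd.DataFrame([[0.5, 0.5, 0.5]] * 3)
    rt = friedman_rank(g)
    assert rt.chi2 == 0.0


def test_matches_scipy_on_random_tables(rng):
    """Dual route: our tie-corrected statistic vs scipy's, 1000 fuzz cases."""
    for _ in range(1000):
        table = rng.random((6, 4))
        rt = friedman_rank(pd.DataFrame(table))
        ref_stat, ref_p = stats.friedmanchisquare(*table.T)
        assert rt.chi2 == pytest.approx(ref_stat, abs=1e-9)
        assert rt.p_value == pytest.approx(ref_p, abs=1e-9)


def test_exact_permutation_matches_enumeration(rng):
    """p_exact equals a brute-force enumeration of all (3!)^3 rank tables."""
    g = pd.DataFrame(rng.random((3, 3)))
    rt = friedman_rank(g, exact=True)

    def brute_chi2(ranks):
        n, k = ranks.shape
        rj = ranks.sum(axis=0)
        return 12.0 * (rj**2).sum() / (n * k * (k + 1)) - 3 * n * (k + 1)

    perms = list(itertools.permutations([1.0, 2.0, 3.0]))
    null = [
        brute_chi2(np.array(combo))
        for combo in itertools.product(perms, repeat=3)
    ]
    expected = np.mean([v >= rt.chi2 - 1e-12 for v in null])
    assert rt.p_exact == pytest.approx(expected, abs=1e-12)


def test_ranking_invariant_under_positive_scaling(rng):
    g = pd.DataFrame(rng.random((4, 5)))
    rt1 = friedman_rank(g)
    rt2 = friedman_rank(g * 3.7)
    pd.testing.assert_frame_equal(rt1.ranks, rt2.ranks)
    assert rt1.chi2 == pytest.approx(rt2.chi2, abs=1e-12)


def test_missing_cells_rejected():
    g = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]])
    with pytest.raises(ValueError, match="missing"):
        friedman_rank(g)


# -- w sensitivity and overfit ----------------------------------------------

def test_w_sensitivity_limits_and_printed_value():
    comp = pd.DataFrame(
        {"rca": [0.962], "rcb": [0.999], "f": [0.932]}, index=["AdaBoost"]
    )
    table = w_sensitivity(comp, weights=(0.0, 0.8, 1.0))
    assert table.loc["AdaBoost", 0.0] == pytest.approx(0.932)
    assert table.loc["AdaBoost", 1.0] == pytest.approx(0.962 * 0.999)
    assert table.loc["AdaBoost", 0.8] == pytest.approx(0.955, abs=5e-4)
    with pytest.raises(ValueError):
        w_sensitivity(comp, weights=(1.2,))


def test_overfit_deltas_and_flags():
    same = {"g": 0.9, "mae": 0.1, "r2": 0.5, "rmse": 0.15}
    report = overfit_check(same, same)
    assert (report.delta == 0).all()
    assert not report.flagged.any()
    report = overfit_check({**same, "g": 0.99}, {**same, "g": 0.80})
    assert report.loc["g", "delta"] == pytest.approx(0.19)
    assert report.loc["g", "flagged"]
    with pytest.raises(ValueError, match="missing"):
        overfit_check({"g": 1.0}, same)


def test_unpruned_tree_flagged_while_linear_fit_is_not():
    """On noisy data a depth-unbounded tree memorises the training split."""
    flags = {"DT": 0, "LR": 0}
    for seed in range(5):
        train = _linear_frame(2000, 100 + seed, noise=0.15)
        test = _linear_frame(800, 200 + seed, noise=0.15)
        for model in ("DT", "LR"):
            prot = pd.DataFrame({"a": train["a"]})
            metrics = {}
            for split, frame in (("train", train), ("test", test)):
                pred = fit_predict(model, train, frame, ["a", "b", "c"], seed=seed)
                panel = metric_panel(frame.eq5i, pred)
                comp = g_components(
                    frame.eq5i, pred, pd.DataFrame({"a": frame["a"]}), seed=seed
                )
                metrics[split] = {"g": comp.g, "mae": panel.mae,
                                  "r2": panel.r2, "rmse": panel.rmse}
            report = overfit_check(metrics["train"], metrics["test"])
            flags[model] += int(report.flagged.any())
    assert flags["DT"] >= 4
    assert flags["LR"] <= 1
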