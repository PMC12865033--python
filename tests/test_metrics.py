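"""The clinically grounded metric suite: truncation, MTAE, RCA/RCB, PPS, F, G."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

import eqmap.metrics as M
from eqmap.metrics import (
    fairness,
    g_components,
    g_score,
    metric_panel,
    mtae,
    pps,
    rca,
    rcb,
    truncated_errors,
)


class TestTruncation:
    def test_hand_computed_example(self):
        ev = truncated_errors((0.9, 0.5), (0.95, 0.40), mcid=0.066)
        np.testing.assert_allclose(ev.truncated, [0.017, -0.067], atol=1e-12)
        assert mtae(ev) == pytest.approx(0.042, abs=1e-12)

    def test_perfect_predictions_truncate_to_zero(self):
        ev = truncated_errors([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert (ev.truncated == 0).all()
        assert mtae(ev) == 0.0

    def test_boundary_error_exactly_half_mcid(self):
        ev = truncated_errors([0.5], [0.533], mcid=0.066)
        assert ev.truncated[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_beyond_band(self):
        ev = truncated_errors(np.zeros(5), np.full(5, 0.033 + 0.02), mcid=0.066)
        assert mtae(ev) == pytest.approx(0.02, abs=1e-12)

    def test_truncated_never_exceeds_raw(self, rng):
        e = rng.normal(0, 0.2, 1000)
        ev = truncated_errors(np.zeros(1000), e)
        assert (np.abs(ev.truncated) <= np.abs(ev.errors) + 1e-15).all()
        assert ((ev.truncated == 0) == (np.abs(ev.errors) <= ev.h + 1e-15)).all()

    def test_hard_zero_strategy_keeps_large_errors_untrimmed(self):
        ev = truncated_errors([0.0, 0.0], [0.02, 0.2], strategy="hard_zero")
        np.testing.assert_allclose(ev.truncated, [0.0, 0.2])

    def test_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            truncated_errors([1, 2], [1])
        with pytest.raises(ValueError, match="finite"):
            truncated_errors([1.0], [np.nan])
        with pytest.raises(ValueError, match="mcid"):
            truncated_errors([1.0], [1.0], mcid=0)


class TestRelativeClinicalMetrics:
    def test_rca_reproduces_printed_mean_row(self):
        # MTAE 0.069 over the 1.848-wide scale with MCID 0.066
        ev = truncated_errors(np.zeros(4), np.full(4, 0.069 + 0.033))
        assert mtae(ev) == pytest.approx(0.069, abs=1e-12)
        assert rca(ev, range_width=1.848) == pytest.approx(0.962, abs=5e-4)

    def test_rca_limits(self):
        perfect = truncated_errors(np.zeros(3), np.zeros(3))
        assert rca(perfect) == 1.0
        worst = truncated_errors(np.zeros(3), np.full(3, 1.815 + 0.033))
        assert rca(worst, range_width=1.848) == pytest.approx(0.0, abs=1e-12)

    def test_rcb_symmetric_errors_cancel(self):
        ev = truncated_errors([0.0, 0.0], [0.083, -0.083])
        assert rcb(ev) == 1.0

    def test_rcb_hand_computed_bias(self):
        ev = truncated_errors(np.zeros(3), np.full(3, 0.133), mcid=0.066)
        np.testing.assert_allclose(ev.truncated, 0.1, atol=1e-12)
        assert rcb(ev, 1.848) == pytest.approx(1 - 0.100 / 1.815, abs=1e-9)

    def test_scaling_errors_up_never_increases_rca(self, rng):
        for _ in range(50):
            e = rng.normal(0, 0.1, 60)
            ev1 = truncated_errors(np.zeros(60), e)
            ev2 = truncated_errors(np.zeros(60), 1.5 * e)
            assert rca(ev2) <= rca(ev1) + 1e-12

    def test_positive_shift_never_increases_rcb(self, rng):
        for _ in range(50):
            e = rng.normal(0.02, 0.1, 60)
            ev1 = truncated_errors(np.zeros(60), e)
            ev2 = truncated_errors(np.zeros(60), e + 0.05)
            assert rcb(ev2) <= rcb(ev1) + 1e-12


class TestPPS:
    def test_constant_target_scores_zero(self):
        assert pps(np.arange(100.0), np.ones(100)) == 0.0

    def test_identity_feature_recovers_target(self, rng):
        """A depth-d tree recovers the identity up to its 2^d-leaf
        resolution: expected skill ~ 1 - (2^-d/4)/0.25 on a uniform
        target, so ~0.94 at the default depth 4 and >0.99 at depth 8."""
        x = rng.uniform(0, 1, 200)
        assert pps(x, x) >= 0.90
        assert pps(x, x, max_depth=8) >= 0.95

    def test_independent_feature_has_no_skill(self):
        scores = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            scores.append(pps(r.normal(size=500), r.normal(size=500), seed=seed))
        assert np.mean(scores) <= 0.05

    def test_matches_brute_force_recomputation(self, rng):
        """Fold-by-fold oracle recomputation agrees to 1e-9 on small n."""
        for n in (24, 37, 50):
            x = rng.uniform(-2, 2, n)
            y = np.sin(x) + rng.normal(0, 0.3, n)
            expected = []
            for tr, te in KFold(4, shuffle=True, random_state=5).split(x):
                tree = DecisionTreeRegressor(max_depth=4, random_state=5)
                tree.fit(x[tr].reshape(-1, 1), y[tr])
                mae_m = np.abs(tree.predict(x[te].reshape(-1, 1)) - y[te]).mean()
                mae_n = np.abs(np.median(y[tr]) - y[te]).mean()
                expected.append(max(0.0, 1 - mae_m / mae_n))
            assert pps(x, y, folds=4, seed=5) == pytest.approx(
                np.mean(expected), abs=1e-9
            )

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            pps(np.arange(5.0), np.arange(5.0), folds=4)


class TestFairnessAndG:
    def test_fairness_is_mean_complement_of_pps(self, monkeypatch):
        values = iter([0.1, 0.2])
        monkeypatch.setattr(M, "pps", lambda *a, **k: next(values))
        ev = truncated_errors(np.zeros(20), np.ones(20) * 0.1)
        f, per_var = fairness(ev, pd.DataFrame({"a": np.arange(20.0),
                                                "b": np.arange(20.0)}))
        assert f == pytest.approx(0.85)
        assert per_var == {"a": 0.1, "b": 0.2}

    def test_fairness_requires_protected_variables(self):
        ev = truncated_errors(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="empty"):
            fairness(ev, pd.DataFrame(index=range(10)))
        with pytest.raises(ValueError, match="rows"):
            fairness(ev, pd.DataFrame({"a": [1.0] * 5}))

    def test_g_reproduces_printed_scenario_means(self):
        assert g_score(0.962, 0.999, 0.932, w=0.8) == pytest.approx(0.955, abs=5e-4)
        assert g_score(0.957, 0.987, 0.577, w=0.8) == pytest.approx(0.871, abs=5e-4)

    def test_g_limits_and_domain(self):
        assert g_score(1, 1, 1, w=0.37) == 1.0
        assert g_score(0.5, 0.5, 0.9, w=0.0) == 0.9
        assert g_score(0.5, 0.5, 0.9, w=1.0) == 0.25
        with pytest.raises(ValueError):
            g_score(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            g_score(0.5, 0.5, 0.5, w=-0.1)

    def test_g_formula_fuzz_stays_in_unit_interval(self, rng):
        vals = rng.uniform(0, 1, (10_000, 4))
        for r_, b, f, w in vals:
            g = g_score(r_, b, f, w)
            assert 0.0 <= g <= 1.0
            assert g == pytest.approx(w * r_ * b + (1 - w) * f, abs=1e-12)

    def test_perfect_predictions_give_g_of_one(self, rng):
        y = rng.uniform(-0.8, 1.0, 120)
        prot = pd.DataFrame({"age": rng.uniform(18, 95, 120),
                             "sex": rng.integers(1, 3, 120).astype(float)})
        for w in (0.0, 0.5, 0.8, 1.0):
            comp = g_components(y, y, prot, w=w)
            assert comp.g == 1.0
            assert comp.rca == comp.rcb == comp.f == 1.0


class TestMetricPanel:
    def test_perfect_and_mean_predictors(self, rng):
        y = rng.uniform(0, 1, 50)
        perfect = metric_panel(y, y)
        assert perfect.mae == 0 and perfect.rmse == 0
        assert perfect.r2 == pytest.approx(1.0)
        mean_pred = metric_panel(y, np.full(50, y.mean()))
        assert mean_pred.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_small_example(self):
        panel = metric_panel([1, 2, 3], [1, 2, 4])
        assert panel.mae == pytest.approx(1 / 3, abs=1e-12)
        assert panel.rmse == pytest.approx(0.5774, abs=5e-5)
        assert panel.mse == pytest.approx(panel.rmse**2, abs=1e-12)

    def test_mcid_truncation_bounds(self, rng):
        for _ in range(200):
            y = rng.uniform(0, 1, 40)
            p = y + rng.normal(0, 0.15, 40)
            panel = metric_panel(y, np.clip(p, -0.848, 1.0))
            assert panel.mtae <= panel.mae + 1e-12
            assert panel.rmse >= panel.mae - 1e-12

    def test_zero_variance_truth_warns(self):
        with pytest.warns(UserWarning, match="variance"):
            panel = metric_panel([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
        assert np.isnan(panel.r2)


def test_metric_invariants_under_fuzz(rng):
    """RCA, RCB in [0,1] and MTAE <= MAE over 10^4 random error vectors."""
    for _ in range(10_000):
        n = int(rng.integers(2, 12))
        y = rng.uniform(-0.848, 1.0, n)
        p = np.clip(y + rng.normal(0, rng.uniform(0.01, 0.8), n), -0.848, 1.0)
        ev = truncated_errors(y, p)
        a, b = rca(ev), rcb(ev)
        assert 0.0 <= a <= 1.0 and 0.0 <= b <= 1.0
        assert mtae(ev) <= np.abs(ev.errors).mean() + 1e-12
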