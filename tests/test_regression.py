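"""Segment models, error metrics, and Cook's-distance diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import luminolpmi as lp
from luminolpmi.regression import deletion_cooks_distances


class TestMetrics:
    def test_wmape_perfect_fit_is_zero(self):
        assert lp.wmape([100.0, 50.0], [100.0, 50.0]) == 0.0

    def test_wmape_hand_value(self):
        assert lp.wmape([100.0, 50.0], [90.0, 60.0]) == pytest.approx(20.0 / 150.0)

    @pytest.mark.parametrize(
        "y, yhat, expected",
        [([100.0], [90.0], 10.0), ([100.0, 200.0], [110.0, 180.0], 10.0)],
    )
    def test_rmspe_hand_values(self, y, yhat, expected):
        assert lp.rmspe(y, yhat) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(1e-3, 1e3),
        y=st.lists(st.floats(1.0, 1e4), min_size=1, max_size=8),
    )
    def test_scale_invariance(self, scale, y):
        y = np.array(y)
        yhat = y * 0.9 + 1.0
        assert lp.wmape(y * scale, yhat * scale) == pytest.approx(lp.wmape(y, yhat), rel=1e-9)
        assert lp.rmspe(y * scale, yhat * scale) == pytest.approx(lp.rmspe(y, yhat), rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lp.wmape([], [])
        with pytest.raises(ValueError):
            lp.rmspe([], [])


class TestFitDecay:
    def test_exact_model_recovery(self):
        x = np.array([0.0, 5.0, 10.0, 20.0])
        y = 100.0 * np.exp(-x / 10.0)
        fit = lp.fit_decay(x, y, fix_x0_at=0.0)
        assert fit.a1 == pytest.approx(100.0, rel=1e-6)
        assert fit.t1 == pytest.approx(10.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.wmape == pytest.approx(0.0, abs=1e-9)

    def test_segment1_time_constant_near_published_value(self, default_model):
        # early-segment fit minus the three flagged outliers
        assert default_model.seg1.t1 == pytest.approx(5.36, abs=0.05)

    def test_refit_from_solution_is_a_fixed_point(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 25, 12))
        y = 500 * np.exp(-x / 6.0) * (1 + 0.1 * rng.standard_normal(12)) + 1.0
        fit = lp.fit_decay(x, y)
        refit = lp.fit_decay(x, y, fix_x0_at=fit.x0, p0=(fit.a1, fit.t1))
        assert refit.a1 == pytest.approx(fit.a1, rel=1e-8)
        assert refit.t1 == pytest.approx(fit.t1, rel=1e-8)

    def test_free_x0_mode_flags_ci_unreliable_but_predicts_identically(self, working23):
        kept = lp.exclude_samples(working23, [1, 2, 5])
        fixed = lp.fit_decay(kept.pmi, kept.ipeak)
        free = lp.fit_decay(kept.pmi, kept.ipeak, fix_x0_at="free")
        assert not free.ci_reliable and fixed.ci_reliable
        np.testing.assert_allclose(
            fixed.predict(kept.pmi), free.predict(kept.pmi), rtol=1e-4
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(lp.FitError):
            lp.fit_decay([1.0, 2.0], [5.0, 3.0])

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError):
            lp.fit_decay([1.0, 2.0, 3.0, 4.0], [5.0, 3.0, 0.0, 1.0])


class TestPredictDecay:
    @pytest.fixture
    def fit(self):
        x = np.array([0.0, 5.0, 10.0, 20.0])
        return lp.fit_decay(x, 100.0 * np.exp(-x / 10.0), fix_x0_at=0.0)

    def test_value_at_x0_is_a1(self, fit):
        assert lp.predict_decay(fit, fit.x0) == pytest.approx(fit.a1, rel=1e-9)

    def test_e_folding(self, fit):
        assert lp.predict_decay(fit, fit.x0 + fit.t1) == pytest.approx(fit.a1 / np.e, rel=1e-9)

    def test_half_life(self, fit):
        x_half = fit.x0 + fit.t1 * np.log(2)
        assert lp.predict_decay(fit, x_half) == pytest.approx(fit.a1 / 2, rel=1e-9)


class TestFitLine:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = lp.fit_line(x, 2 * x + 1)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.wmape == pytest.approx(0.0, abs=1e-12)

    def test_hand_normal_equations(self):
        # Sxy/Sxx = 3/2; intercept = ybar - slope*xbar = 7/3 - 3/2 = 5/6
        fit = lp.fit_line([0.0, 1.0, 2.0], [1.0, 2.0, 4.0])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(5.0 / 6.0)

    def test_matches_closed_form_on_random_input(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 20)
        y = 3 - 0.5 * x + rng.standard_normal(20)
        fit = lp.fit_line(x, y)
        # normal-equations oracle
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert abs(np.sum(fit.residuals)) < 1e-8

    def test_r2_nonnegative_on_training_data(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 15)
        y = rng.uniform(1, 2, 15)  # no relation at all
        assert lp.fit_line(x, y).r2 >= 0.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(lp.FitError, match="degenerate"):
            lp.fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_published_linear_segment_r2(self, working23):
        late = working23.subset([18, 19, 20, 21, 22, 23])
        fit = lp.fit_line(late.pmi, late.ipeak)
        assert fit.r2 == pytest.approx(0.8030, abs=0.005)


class TestCooksDistance:
    def test_zero_residual_point_has_zero_distance(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2 * x + 1.0
        y[2] += 0.0  # on the line
        y[4] += 3.0
        rep = lp.cooks_distances(x, y, "line")
        # the point with (near) zero residual contributes (near) zero distance
        res = lp.fit_line(x, y).residuals
        i = int(np.argmin(np.abs(res)))
        assert rep.distances[i] == pytest.approx(0.0, abs=1e-6)

    def test_deletion_definition_matches_hat_matrix_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 12)
        y = 5 + 2 * x + rng.standard_normal(12)
        d_del = deletion_cooks_distances(x, y, "line")
        # closed-form oracle e_i^2 h_ii / (p s^2 (1-h_ii)^2)
        X = np.column_stack([np.ones_like(x), x])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        h = np.diag(H)
        e = y - H @ y
        s2 = e @ e / (12 - 2)
        d_closed = e**2 * h / (2 * s2 * (1 - h) ** 2)
        np.testing.assert_allclose(d_del, d_closed, atol=1e-10)
        # and the report path (classical formula) agrees too
        np.testing.assert_allclose(
            lp.cooks_distances(x, y, "line").distances, d_closed, atol=1e-10
        )

    def test_exploratory_decay_screen_ranks_samples_1_2_5_highest(self, working23):
        rep = lp.cooks_distances(working23.pmi, working23.ipeak, "decay", ids=working23.ids)
        top3 = set(rep.ids[np.argsort(-rep.distances)[:3]])
        assert top3 == {1, 2, 5}


class TestFlagOutliers:
    def test_all_zero_distances_flag_nothing_under_threshold_rule(self):
        rep = lp.InfluenceReport(
            ids=np.arange(1, 6), distances=np.zeros(5), model_kind="line"
        )
        assert lp.flag_outliers(rep, lp.ThresholdOverN()) == frozenset()

    def test_top_k_on_exploratory_fit_returns_1_2_5(self, working23):
        rep = lp.cooks_distances(working23.pmi, working23.ipeak, "decay", ids=working23.ids)
        assert lp.flag_outliers(rep, lp.TopK(3)) == {1, 2, 5}
        assert rep.rule == "top_k(3)"

    def test_threshold_rule_cutoff_is_4_over_n(self):
        d = np.array([0.25, 0.19, 0.21, 0.05] + [0.0] * 16)
        rep = lp.InfluenceReport(ids=np.arange(1, 21), distances=d, model_kind="line")
        flagged = lp.flag_outliers(rep, lp.ThresholdOverN())
        assert rep.threshold == pytest.approx(0.2)
        assert flagged == {1, 3}

    def test_k_larger_than_n_rejected(self):
        rep = lp.InfluenceReport(ids=np.arange(1, 4), distances=np.zeros(3), model_kind="line")
        with pytest.raises(ValueError):
            lp.flag_outliers(rep, lp.TopK(4))


class TestParameterRecovery:
    def test_t1_recovery_and_ci_coverage_under_multiplicative_noise(self):
        """sigma=0.1, n=15: median |t1_hat - t1|/t1 <= 15%, coverage in [88%, 99%]."""
        true_t1 = 6.0
        rel_err, covered = [], 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.uniform(0.0, 25.0, 15))
            mu = 1000.0 * np.exp(-x / true_t1)
            y = np.clip(mu * (1 + 0.1 * rng.standard_normal(15)), 1e-6, None)
            fit = lp.fit_decay(x, y, fix_x0_at=0.0)
            rel_err.append(abs(fit.t1 - true_t1) / true_t1)
            lo, hi = fit.ci95[1]
            covered += lo <= true_t1 <= hi
        assert np.median(rel_err) <= 0.15
        assert 0.88 * reps <= covered <= 0.99 * reps
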