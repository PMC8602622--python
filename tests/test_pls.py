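import numpy as np
import pytest

from aerometab import (
    build_response,
    cross_validate_q2,
    fit_pls,
    permutation_validate,
)
from aerometab.pls import export_scores, _fold_assignment

from conftest import make_design


def centered(rng, n, J):
    X = rng.standard_normal((n, J))
    return X - X.mean(axis=0)


class TestBuildResponse:
    def test_four_class_one_hot_counts_and_centering(self):
        design = make_design((10, 10, 6, 8))
        Y = build_response(design, "four_class")
        assert Y.shape == (34, 4)
        np.testing.assert_allclose(Y.sum(axis=0), 0.0, atol=1e-12)
        counts = (Y > 0).sum(axis=0)  # positive entries mark class membership
        np.testing.assert_array_equal(counts, [10, 10, 6, 8])

    def test_capacity_mode_two_values_sum_zero(self):
        design = make_design((5, 5, 5, 5))
        y = build_response(design, "capacity")
        assert y.shape == (20, 1)
        assert len(np.unique(y)) == 2
        assert y.sum() == pytest.approx(0.0)

    def test_speed_mode_standardized(self):
        rng = np.random.default_rng(0)
        design = make_design((5, 5, 5, 5), speed=rng.uniform(10, 40, 20))
        y = build_response(design, "speed")
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std(ddof=1) == pytest.approx(1.0)

    def test_speed_mode_without_speed_errors(self):
        design = make_design((2, 2, 2, 2))
        with pytest.raises(ValueError):
            build_response(design, "speed")


class TestFitPLS:
    def test_exact_linear_response_r2y_one(self):
        # y in the span of a rank-2 X is fit exactly by two components
        rng = np.random.default_rng(1)
        latent = centered(rng, 20, 2)
        X = latent @ rng.standard_normal((2, 5))
        y = latent @ np.array([1.5, -0.7])
        with np.errstate(all="ignore"):
            model = fit_pls(X, y[:, None], n_components=2)
        assert model.r2y[-1] == pytest.approx(1.0, abs=1e-10)
        # orthonormal X with y proportional to one column: exact in 1 component
        Q, _ = np.linalg.qr(centered(rng, 20, 4))
        y1 = 3.0 * Q[:, 2]
        model1 = fit_pls(Q, y1[:, None], n_components=1)
        assert model1.r2y[-1] == pytest.approx(1.0, abs=1e-10)

    def test_one_component_weight_equals_normalized_xty(self):
        rng = np.random.default_rng(2)
        X = centered(rng, 25, 8)
        y = centered(rng, 25, 1)
        model = fit_pls(X, y, n_components=1)
        expected = X.T @ y[:, 0]
        expected /= np.linalg.norm(expected)
        sign = np.sign(expected[np.argmax(np.abs(expected))])
        np.testing.assert_allclose(model.weights[:, 0], sign * expected, atol=1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        X = centered(rng, 30, 12)
        Y = centered(rng, 30, 3)
        model = fit_pls(X, Y, n_components=4)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_full_rank_single_response_reproduces_ols(self):
        rng = np.random.default_rng(4)
        X = centered(rng, 30, 6)
        y = centered(rng, 30, 1)
        model = fit_pls(X, y, n_components=6)
        pls_pred = X @ model.coefficients
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(pls_pred, X @ beta_ols, atol=1e-8)

    def test_deflation_conserves_x_sum_of_squares(self):
        rng = np.random.default_rng(5)
        X = centered(rng, 25, 10)
        Y = centered(rng, 25, 2)
        model = fit_pls(X, Y, n_components=3)
        explained = sum(
            np.linalg.norm(np.outer(model.x_scores[:, a], model.x_loadings[:, a])) ** 2
            for a in range(3)
        )
        residual = (1 - model.r2x[-1]) * (X ** 2).sum()
        assert explained + residual == pytest.approx((X ** 2).sum(), rel=1e-8)

    def test_r2_curves_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        X = centered(rng, 20, 8)
        Y = centered(rng, 20, 4)
        model = fit_pls(X, Y, n_components=5)
        for curve in (model.r2x, model.r2y):
            assert np.all(curve >= -1e-12) and np.all(curve <= 1 + 1e-12)
            assert np.all(np.diff(curve) >= -1e-12)

    def test_components_beyond_rank_truncated_with_warning(self):
        rng = np.random.default_rng(7)
        X = centered(rng, 10, 2)
        Y = centered(rng, 10, 1)
        with pytest.warns(RuntimeWarning):
            model = fit_pls(X, Y, n_components=5)
        assert model.n_components <= 2

    def test_zero_variance_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(np.zeros((5, 3)), np.ones((5, 1)) - 1.0)


class TestVIP:
    def test_single_predictor_vip_exactly_one(self):
        rng = np.random.default_rng(8)
        X = centered(rng, 15, 1)
        y = 2 * X + 0.1 * centered(rng, 15, 1)
        model = fit_pls(X, y, n_components=1)
        assert model.vip[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_predictors_equal_vip(self):
        rng = np.random.default_rng(9)
        x = centered(rng, 20, 1)
        X = np.hstack([x, x])
        y = x + 0.05 * centered(rng, 20, 1)
        model = fit_pls(X, y, n_components=1)
        assert model.vip[0] == pytest.approx(model.vip[1], abs=1e-12)

    @pytest.mark.parametrize("seed,J,M,A", [(0, 5, 1, 2), (1, 12, 3, 3), (2, 30, 4, 2)])
    def test_mean_squared_vip_is_one(self, seed, J, M, A):
        rng = np.random.default_rng(seed)
        X = centered(rng, 25, J)
        Y = centered(rng, 25, M)
        model = fit_pls(X, Y, n_components=A)
        assert float((model.vip ** 2).sum()) == pytest.approx(J, abs=1e-8)


class TestCrossValidation:
    def test_noiseless_linear_loo_q2_near_one(self):
        rng = np.random.default_rng(10)
        X = centered(rng, 20, 4)
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        q2 = cross_validate_q2(X, y[:, None], n_components=4, scheme="loo")
        assert q2[-1] == pytest.approx(1.0, abs=1e-6)

    def test_null_response_q2_mostly_nonpositive(self):
        rng = np.random.default_rng(11)
        neg = 0
        for i in range(20):
            X = centered(rng, 24, 10)
            y = centered(rng, 24, 1)
            q2 = cross_validate_q2(X, y, n_components=2, folds=6, seed=i)
            neg += q2[-1] <= 0
        assert neg >= 13

    def test_q2_not_above_r2y(self):
        rng = np.random.default_rng(12)
        ok = 0
        for i in range(30):
            X = centered(rng, 20, 8)
            y = X[:, :2] @ np.array([1.0, 1.0]) + rng.standard_normal(20)
            y = (y - y.mean())[:, None]
            model = fit_pls(X, y, n_components=2)
            q2 = cross_validate_q2(X, y, n_components=2, folds=5, seed=i)
            ok += q2[-1] <= model.r2y[-1] + 1e-12
        assert ok >= 30 * 0.99

    def test_training_split_losing_class_errors(self):
        # a singleton class must vanish from one training split
        rng = np.random.default_rng(13)
        X = centered(rng, 11, 5)
        labels = np.array(["a"] * 10 + ["b"])
        Y = np.column_stack([(labels == "a") - 10 / 11, (labels == "b") - 1 / 11])
        with pytest.raises(ValueError, match="stratified"):
            cross_validate_q2(X, Y, 2, folds=3, scheme="venetian_blinds",
                              labels=labels)

    def test_stratified_folds_keep_all_classes(self):
        labels = np.repeat(["a", "b", "c"], [10, 6, 8])
        assign = _fold_assignment(24, 3, "random", seed=0, labels=labels)
        for f in range(3):
            assert set(labels[assign != f]) == {"a", "b", "c"}


class TestPermutationValidation:
    def test_g1_pvalue_is_half_or_one(self):
        rng = np.random.default_rng(14)
        X = centered(rng, 16, 6)
        y = centered(rng, 16, 1)
        res = permutation_validate(X, y, n_components=2, G=1, folds=4, seed=0)
        assert res.p_value in (0.5, 1.0)

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(15)
        X = centered(rng, 10, 4)
        with pytest.raises(ValueError):
            permutation_validate(X, np.zeros((10, 1)), G=5)

    def test_planted_separation_detected(self, serum_processed):
        processed, design, _ = serum_processed
        Y = build_response(design, "four_class")
        res = permutation_validate(processed.values, Y, n_components=2, G=49,
                                   folds=7, seed=2, labels=design.groups)
        assert res.p_value == pytest.approx(1.0 / 50.0)
        assert res.q2_intercept < 0
        assert res.observed_q2 > 0

    def test_intercept_recomputable_from_stored_points(self, serum_processed):
        processed, design, _ = serum_processed
        Y = build_response(design, "capacity")
        res = permutation_validate(processed.values, Y, n_components=2, G=20,
                                   folds=7, seed=3, labels=design.groups)
        pts = res.points_table()
        line = np.polyfit(pts["similarity"], pts["q2"], 1)
        assert np.polyval(line, 0.0) == pytest.approx(res.q2_intercept, abs=1e-12)
        assert 1.0 / 21.0 <= res.p_value <= 1.0


class TestScores:
    def test_score_table_passthrough(self, serum_processed):
        processed, design, _ = serum_processed
        Y = build_response(design, "four_class")
        model = fit_pls(processed.values, Y, n_components=2)
        table = export_scores(model, design)
        assert len(table) == processed.n_samples
        np.testing.assert_array_equal(table["t1"], model.x_scores[:, 0])
        np.testing.assert_array_equal(table["t2"], model.x_scores[:, 1])
        assert set(table["group"]) <= {"HCR-Y", "LCR-Y", "HCR-O", "LCR-O"}

    def test_single_component_model_rejected(self):
        rng = np.random.default_rng(16)
        X = centered(rng, 12, 4)
        y = centered(rng, 12, 1)
        model = fit_pls(X, y, n_components=1)
        with pytest.raises(ValueError):
            export_scores(model, make_design((3, 3, 3, 3)))

    def test_separated_groups_lie_apart_on_t1(self):
        """Strong planted effects push group centroids > 2 pooled SDs apart."""
        from aerometab import SimulationConfig, align, preprocess_matrix, simulate_study

        cfg = SimulationConfig(seed=33, effect_capacity=2.5, frac_affected=0.3,
                               tissues={"serum": 60})
        matrices, design, _ = simulate_study(cfg)
        matrix, design = align(matrices["serum"], design)
        processed, _ = preprocess_matrix(matrix, design)
        Y = build_response(design, "capacity")
        model = fit_pls(processed.values, Y, n_components=2)
        t1 = model.x_scores[:, 0]
        hcr = design.capacity == "HCR"
        pooled = np.sqrt((t1[hcr].var(ddof=1) + t1[~hcr].var(ddof=1)) / 2)
        assert abs(t1[hcr].mean() - t1[~hcr].mean()) > 2 * pooled
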