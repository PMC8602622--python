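import numpy as np
import pytest

from aerometab import bh_fdr, fit_group_model, fit_speed_model, run_univariate_suite

from conftest import make_design


class TestGroupModel:
    def test_dummy_coding_recovers_exact_cell_means(self):
        # cell means (LCR-Y, HCR-Y, LCR-O, HCR-O) = (0, 0, 0, delta), no noise
        design = make_design((4, 4, 4, 4))
        delta = 2.5
        groups = design.groups
        values = np.where(groups == "HCR-O", delta, 0.0)
        row = fit_group_model(values, design)
        assert row["beta_capacity"] == pytest.approx(0.0, abs=1e-12)
        assert row["beta_age"] == pytest.approx(0.0, abs=1e-12)
        assert row["beta_interaction"] == pytest.approx(delta, abs=1e-12)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        design = make_design((10, 10, 6, 8))
        cap, old = design.capacity_indicator, design.age_indicator
        X = sm.add_constant(np.column_stack([cap, old, cap * old]))
        for _ in range(25):
            y = rng.standard_normal(34) + rng.choice([0, 1]) * cap
            row = fit_group_model(y, design)
            fit = sm.OLS(y, X).fit()
            np.testing.assert_allclose(
                [row["beta_capacity"], row["beta_age"], row["beta_interaction"]],
                fit.params[1:], atol=1e-10)
            np.testing.assert_allclose(
                [row["p_capacity"], row["p_age"], row["p_interaction"]],
                fit.pvalues[1:], atol=1e-10)
            # joint 3-df F of the whole design block vs intercept-only
            f_sm = fit.f_test(np.eye(4)[1:])
            assert row["joint_F"] == pytest.approx(float(f_sm.fvalue), abs=1e-8)
            assert row["joint_p"] == pytest.approx(float(f_sm.pvalue), abs=1e-8)

    def test_empty_cell_rejected(self):
        design = make_design((5, 5, 5, 5))
        design.table.loc[design.groups == "HCR-O", "age"] = "Y"
        with pytest.raises(ValueError):
            fit_group_model(np.arange(20.0), design)

    def test_null_type_one_error_near_nominal(self):
        design = make_design((10, 10, 6, 8))
        rng = np.random.default_rng(1)
        p = np.array([
            fit_group_model(rng.standard_normal(34), design)["joint_p"]
            for _ in range(500)
        ])
        assert 0.03 <= (p < 0.05).mean() <= 0.075


class TestSpeedModel:
    def test_full_model_sse_never_exceeds_reduced(self):
        rng = np.random.default_rng(2)
        design = make_design((10, 10, 6, 8))
        cap, old = design.capacity_indicator, design.age_indicator
        for _ in range(10):
            speed = 20 + 10 * cap + rng.standard_normal(34)
            met = rng.standard_normal(34)
            X_red = np.column_stack([np.ones(34), old, cap, old * cap])
            X_full = np.column_stack([X_red, met, met * old, met * cap, met * old * cap])
            sse_red = np.linalg.lstsq(X_red, speed, rcond=None)[1][0]
            sse_full_arr = np.linalg.lstsq(X_full, speed, rcond=None)[1]
            sse_full = sse_full_arr[0] if len(sse_full_arr) else 0.0
            assert sse_full <= sse_red + 1e-10
            row = fit_speed_model(speed, met, design)
            assert row["joint_F"] >= 0

    def test_matches_statsmodels_partial_f(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        design = make_design((10, 10, 6, 8))
        cap, old = design.capacity_indicator, design.age_indicator
        speed = 20 + 12 * cap + rng.standard_normal(34) * 2
        met = rng.standard_normal(34)
        row = fit_speed_model(speed, met, design)
        X_full = sm.add_constant(np.column_stack(
            [old, cap, old * cap, met, met * old, met * cap, met * old * cap]))
        fit = sm.OLS(speed, X_full).fit()
        contrast = np.zeros((4, 8))
        contrast[np.arange(4), np.arange(4, 8)] = 1.0
        f_sm = fit.f_test(contrast)
        assert row["joint_F"] == pytest.approx(float(f_sm.fvalue), abs=1e-8)
        assert row["joint_p"] == pytest.approx(float(f_sm.pvalue), abs=1e-8)

    def test_planted_metabolite_association_detected(self):
        rng = np.random.default_rng(4)
        design = make_design((10, 10, 6, 8))
        cap, old = design.capacity_indicator, design.age_indicator
        hits = 0
        for _ in range(20):
            met = rng.standard_normal(34)
            speed = 20 + 10 * cap - 2 * old + 1.0 * met + rng.standard_normal(34) * 0.5
            row = fit_speed_model(speed, met, design)
            hits += row["joint_p"] < 0.001
        assert hits >= 18

    def test_constant_metabolite_flagged_not_fatal(self):
        design = make_design((10, 10, 6, 8))
        rng = np.random.default_rng(5)
        speed = 20 + rng.standard_normal(34)
        row = fit_speed_model(speed, np.ones(34), design)
        assert row["singular"]
        assert np.isnan(row["joint_p"])


class TestBHFDR:
    def test_equal_pvalues_unchanged(self):
        p = np.full(10, 0.01)
        np.testing.assert_allclose(bh_fdr(p), 0.01)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.04, 0.2]), [0.015, 0.06, 0.2], atol=1e-12)

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.03])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.03]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm, atol=1e-12)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(size=50))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p - 1e-15)


class TestSuite:
    def test_row_counts_and_fdr_column(self, serum_processed):
        processed, design, _ = serum_processed
        group_table, speed_table = run_univariate_suite(processed, design)
        assert len(group_table) == processed.n_metabolites
        assert len(speed_table) == processed.n_metabolites
        valid = speed_table.dropna(subset=["joint_p"])
        assert (valid["fdr_q"] >= valid["joint_p"] - 1e-15).all()

    def test_without_speed_column_speed_table_empty(self, serum_processed):
        processed, design, _ = serum_processed
        stripped = design.subset_samples(design.sample_ids)
        stripped.table = stripped.table.drop(columns=["speed"])
        group_table, speed_table = run_univariate_suite(processed, stripped)
        assert len(group_table) == processed.n_metabolites
        assert speed_table.empty

    def test_planted_interaction_effects_enrich_small_joint_p(self):
        from aerometab import SimulationConfig, align, preprocess_matrix, simulate_study

        cfg = SimulationConfig(seed=40, effect_capacity=0, effect_age=0,
                               effect_interaction=1.5, tissues={"serum": 80})
        matrices, design, truth = simulate_study(cfg)
        matrix, design = align(matrices["serum"], design)
        processed, _ = preprocess_matrix(matrix, design)
        group_table, _ = run_univariate_suite(processed, design)
        planted = truth.affected("serum", "interaction")
        ranked = group_table.sort_values("joint_p")["metabolite"]
        top = set(ranked.head(len(planted)))
        assert len(top & planted) >= len(planted) // 2
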