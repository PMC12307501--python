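import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ahaging.clock import (
    ClockConfig,
    ClockModel,
    calibrate_unbiased,
    classify_agers,
    compute_delta_age_and_mae,
    fit_aging_clock,
    fit_ridge_clock,
    lasso_stability_selection,
    predict_age,
    protein_auc,
    random_signature_null,
    ridge_fit,
    split_train_test,
)
from ahaging.core_data import impute_missing
from ahaging.errors import ConfigurationError, ValidationError
from ahaging.synthetic import CohortSimConfig, generate_cohort

from conftest import make_meta, make_table


class TestSplit:
    def test_partition_covers_cohort(self):
        meta = make_meta([70.0] * 33 + [25.0] * 19, ["older"] * 33 + ["young"] * 19)
        cfg = ClockConfig(n_train=33, seed=5)
        train, test = split_train_test(meta, cfg)
        assert len(train) == 33 and len(test) == 19
        assert sorted(train + test) == sorted(meta.sample_ids)
        assert not set(train) & set(test)

    def test_deterministic_given_seed(self):
        meta = make_meta([70.0] * 8 + [25.0] * 4, ["older"] * 8 + ["young"] * 4)
        a = split_train_test(meta, ClockConfig(n_train=7, seed=1))
        b = split_train_test(meta, ClockConfig(n_train=7, seed=1))
        c = split_train_test(meta, ClockConfig(n_train=7, seed=2))
        assert a == b
        assert a != c

    def test_train_size_must_leave_test_samples(self):
        meta = make_meta([70.0] * 4, ["older"] * 4)
        with pytest.raises(ValidationError):
            split_train_test(meta, ClockConfig(n_train=4))


class TestRidgeFit:
    def test_univariate_closed_form(self):
        # beta = sum(x*y) / (sum(x^2) + lam) on centred data
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([-1.0, 0.0, 1.0])
        beta, intercept = ridge_fit(X, y, lam=2.0)
        assert beta[0] == pytest.approx(2.0 / 4.0)
        assert intercept == pytest.approx(0.0)

    def test_lambda_zero_reduces_to_ols(self, rng):
        X = rng.normal(size=(30, 3))
        true_beta = np.array([1.0, -2.0, 0.5])
        y = X @ true_beta + 4.0
        beta, intercept = ridge_fit(X, y, lam=0.0)
        np.testing.assert_allclose(beta, true_beta, atol=1e-8)
        assert intercept == pytest.approx(4.0, abs=1e-8)

    def test_huge_lambda_shrinks_to_mean(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.uniform(40, 80, size=30)
        beta, intercept = ridge_fit(X, y, lam=1e12)
        np.testing.assert_allclose(beta, 0.0, atol=1e-6)
        assert intercept == pytest.approx(y.mean(), abs=1e-4)

    def test_training_residuals_orthogonal_at_lambda_zero(self, rng):
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        beta, intercept = ridge_fit(X, y, lam=0.0)
        resid = y - (X @ beta + intercept)
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)


class TestStabilitySelection:
    def planted(self, seed=0, n=40, p=20, informative=2):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"P{i}" for i in range(p)])
        age = 50 + 10 * X["P0"] - 8 * X["P1"] + rng.normal(scale=0.5, size=n)
        return X, pd.Series(age)

    def test_planted_features_dominate_signature(self):
        X, y = self.planted()
        cfg = ClockConfig(n_reps=25, cv_folds=5, seed=3)
        freq, signature = lasso_stability_selection(X, y, cfg)
        assert {"P0", "P1"} <= set(signature)
        assert freq["P0"] == cfg.n_reps and freq["P1"] == cfg.n_reps

    def test_signature_threshold_is_strict_majority(self):
        X, y = self.planted(seed=1)
        cfg = ClockConfig(n_reps=10, cv_folds=5, seed=4)
        freq, signature = lasso_stability_selection(X, y, cfg)
        assert set(signature) == set(freq.index[freq > cfg.n_reps / 2])

    def test_deterministic_given_seed(self):
        X, y = self.planted(seed=2)
        cfg = ClockConfig(n_reps=10, cv_folds=5, seed=6)
        freq_a, sig_a = lasso_stability_selection(X, y, cfg)
        freq_b, sig_b = lasso_stability_selection(X, y, cfg)
        pd.testing.assert_series_equal(freq_a, freq_b)
        assert sig_a == sig_b

    def test_zero_variance_feature_rejected(self):
        X, y = self.planted(seed=3)
        X["P5"] = 1.0
        with pytest.raises(ValidationError, match="P5"):
            lasso_stability_selection(X, y, ClockConfig(n_reps=2, cv_folds=5))

    def test_single_rep_runs(self):
        X, y = self.planted(seed=4)
        freq, _ = lasso_stability_selection(X, y, ClockConfig(n_reps=1, cv_folds=5))
        assert freq.max() <= 1


class TestCalibration:
    def test_hand_computed_line_and_unbiased_ages(self):
        chron = pd.Series({"S1": 20.0, "S2": 50.0, "S3": 80.0})
        # predicted sits exactly on 2/3 * age + 50/3
        predicted = (2.0 * chron + 50.0) / 3.0
        intercept, slope, unbiased = calibrate_unbiased(predicted, chron, chron.index)
        assert slope == pytest.approx(2.0 / 3.0)
        assert intercept == pytest.approx(50.0 / 3.0)
        np.testing.assert_allclose(unbiased, [20.0, 50.0, 80.0], atol=1e-10)

    def test_mean_delta_age_zero_over_calibration_samples(self, rng):
        n = 40
        chron = pd.Series(rng.uniform(19, 91, n), index=[f"S{i}" for i in range(n)])
        predicted = 0.6 * chron + 12 + pd.Series(rng.normal(scale=4, size=n),
                                                 index=chron.index)
        _, _, unbiased = calibrate_unbiased(predicted, chron, chron.index)
        delta, _ = compute_delta_age_and_mae(unbiased, chron)
        assert delta.mean() == pytest.approx(0.0, abs=1e-8)

    def test_constant_chronological_age_rejected(self):
        chron = pd.Series({"S1": 50.0, "S2": 50.0, "S3": 50.0})
        with pytest.raises(ValidationError):
            calibrate_unbiased(chron * 0 + 1, chron, chron.index)

    def test_flat_predictions_rejected(self):
        chron = pd.Series({"S1": 20.0, "S2": 50.0, "S3": 80.0})
        predicted = pd.Series(55.0, index=chron.index)
        with pytest.raises(ValidationError):
            calibrate_unbiased(predicted, chron, chron.index)

    def test_mae_hand_example(self):
        chron = pd.Series({"S1": 30.0, "S2": 60.0})
        unbiased = pd.Series({"S1": 33.0, "S2": 55.0})
        delta, mae = compute_delta_age_and_mae(unbiased, chron)
        assert delta.loc["S1"] == pytest.approx(3.0)
        assert delta.loc["S2"] == pytest.approx(-5.0)
        assert mae == pytest.approx(4.0)


class TestClassify:
    def test_threshold_boundaries(self):
        delta = pd.Series({"a": -5.0, "b": 5.0, "c": 1.9, "d": -1.99,
                           "e": 3.0, "f": -3.0, "g": 0.0})
        out = classify_agers(delta)
        assert out.to_dict() == {"a": "DA", "b": "AA", "c": "CA", "d": "CA",
                                 "e": "unclassified", "f": "unclassified", "g": "CA"}

    def test_custom_thresholds(self):
        delta = pd.Series({"a": -3.5, "b": 3.5})
        cfg = ClockConfig(da_threshold=-3.0, aa_threshold=3.0, ca_band=1.0)
        out = classify_agers(delta, cfg)
        assert out.to_dict() == {"a": "DA", "b": "AA"}

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            ClockConfig(da_threshold=1.0)


class TestAUC:
    def groups(self, n_old, n_young):
        labels = ["older"] * n_old + ["young"] * n_young
        idx = [f"S{i}" for i in range(n_old + n_young)]
        return pd.Series(labels, index=idx), idx

    def test_perfect_separation(self):
        groups, idx = self.groups(3, 3)
        expr = pd.Series([4.0, 5, 6, 1, 2, 3], index=idx)
        assert protein_auc(expr, groups) == pytest.approx(1.0)
        assert protein_auc(-expr, groups) == pytest.approx(0.0)

    def test_all_tied_gives_half(self):
        groups, idx = self.groups(2, 2)
        expr = pd.Series(1.0, index=idx)
        assert protein_auc(expr, groups) == pytest.approx(0.5)

    def test_matches_scipy_u_statistic(self, rng):
        groups, idx = self.groups(12, 8)
        expr = pd.Series(rng.normal(size=20), index=idx)
        u = sps.mannwhitneyu(expr.iloc[:12], expr.iloc[12:],
                             alternative="two-sided").statistic
        assert protein_auc(expr, groups) == pytest.approx(u / (12 * 8))

    def test_empty_group_rejected(self):
        groups, idx = self.groups(3, 0)
        expr = pd.Series([1.0, 2, 3], index=idx)
        with pytest.raises(ValidationError):
            protein_auc(expr, groups)


def small_cohort(seed=7):
    cfg = CohortSimConfig(seed=seed, n_proteins=40, n_trend_proteins=0,
                          n_clock_proteins=8, sigma_noise=0.3, sigma_delta=6.0)
    table, meta, truth = generate_cohort(cfg)
    return impute_missing(table), meta, truth


class TestRidgeClock:
    def test_fixed_lambda_predictions_track_age(self):
        table, meta, truth = small_cohort()
        cfg = ClockConfig(ridge_lambda=10.0, seed=0)
        train, test = split_train_test(meta, cfg)
        model = fit_ridge_clock(table, meta, truth.clock_proteins, cfg, train)
        pred = predict_age(model, table, meta)
        r = sps.pearsonr(pred.loc[test], meta.age.loc[test])[0]
        assert r > 0.7

    def test_empty_signature_rejected_with_hint(self):
        table, meta, _ = small_cohort()
        cfg = ClockConfig(seed=0)
        train, _ = split_train_test(meta, cfg)
        with pytest.raises(ValidationError, match="frequency threshold"):
            fit_ridge_clock(table, meta, [], cfg, train)

    def test_model_json_roundtrip(self, tmp_path):
        table, meta, truth = small_cohort()
        cfg = ClockConfig(ridge_lambda=5.0, seed=0)
        train, _ = split_train_test(meta, cfg)
        model = fit_ridge_clock(table, meta, truth.clock_proteins, cfg, train)
        model.calibration_intercept, model.calibration_slope = 1.0, 0.9
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClockModel.from_json(path)
        pred_a = predict_age(model, table, meta)
        pred_b = predict_age(back, table, meta)
        np.testing.assert_allclose(pred_a, pred_b, atol=1e-12)
        assert back.calibration_slope == 0.9


class TestRandomSignatureNull:
    def test_deterministic_and_in_range(self):
        table, meta, truth = small_cohort()
        cfg = ClockConfig(ridge_lambda=10.0, seed=3)
        train, test = split_train_test(meta, cfg)
        a = random_signature_null(table, meta, size=5, n_draws=4, cfg=cfg,
                                  train_ids=train, test_ids=test,
                                  exclude=truth.clock_proteins)
        b = random_signature_null(table, meta, size=5, n_draws=4, cfg=cfg,
                                  train_ids=train, test_ids=test,
                                  exclude=truth.clock_proteins)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.abs(a) <= 1.0)

    def test_size_larger_than_pool_rejected(self):
        table, meta, _ = small_cohort()
        cfg = ClockConfig(ridge_lambda=10.0, seed=3)
        train, test = split_train_test(meta, cfg)
        with pytest.raises(ValidationError):
            random_signature_null(table, meta, size=1000, n_draws=1, cfg=cfg,
                                  train_ids=train, test_ids=test)


class TestFitAgingClock:
    def test_end_to_end_on_planted_clock_proteins(self):
        table, meta, truth = small_cohort(seed=11)
        cfg = ClockConfig(n_reps=20, cv_folds=5, seed=11)
        result = fit_aging_clock(table, meta, truth.clock_proteins, cfg)
        # calibrated on train => mean train delta is zero
        train_delta = result.assessments.loc[result.train_ids, "delta_age"]
        assert train_delta.mean() == pytest.approx(0.0, abs=1e-8)
        assert result.test_r > 0.5
        assert set(result.assessments["split"]) == {"train", "test"}
        assert result.assessments.loc[result.train_ids, "split"].eq("train").all()
        classes = set(result.assessments["ager_class"])
        assert classes <= {"DA", "AA", "CA", "unclassified"}

    def test_calibrate_on_all_zeroes_cohort_mean_delta(self):
        table, meta, truth = small_cohort(seed=12)
        cfg = ClockConfig(n_reps=10, cv_folds=5, seed=12, calibrate_on="all")
        result = fit_aging_clock(table, meta, truth.clock_proteins, cfg)
        assert result.assessments["delta_age"].mean() == pytest.approx(0.0, abs=1e-8)
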