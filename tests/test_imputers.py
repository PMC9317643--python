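import numpy as np
import pandas as pd
import pytest

from pairimpute import ImputerSettings, impute_matrix
from pairimpute.imputers import (
    fit_censored_column,
    fit_em_normal,
    impute_emb,
    impute_half_minimum,
    impute_knn,
    impute_qrilc,
    impute_random_forest,
)

METHODS = ["HM", "KNN", "RF", "EMB", "QRILC"]


def _df(array):
    array = np.asarray(array, dtype=float)
    return pd.DataFrame(
        array,
        index=[f"met{i}" for i in range(array.shape[0])],
        columns=[f"s{j}" for j in range(array.shape[1])],
    )


class TestUniformContract:
    """Properties every imputation method must satisfy."""

    @pytest.mark.parametrize("method", METHODS)
    def test_observed_preserved_and_complete(self, small_masked_matrix, fast_settings, method):
        out = impute_matrix(small_masked_matrix, method, fast_settings)
        observed = ~small_masked_matrix.isna().to_numpy()
        np.testing.assert_array_equal(
            out.to_numpy()[observed], small_masked_matrix.to_numpy()[observed]
        )
        assert not out.isna().any().any()

    @pytest.mark.parametrize("method", METHODS)
    def test_complete_input_returned_unchanged(self, fast_settings, method):
        rng = np.random.default_rng(3)
        matrix = _df(rng.normal(5, 1, size=(12, 9)))
        out = impute_matrix(matrix, method, fast_settings)
        pd.testing.assert_frame_equal(out, matrix)

    @pytest.mark.parametrize("method", ["RF", "EMB", "QRILC"])
    def test_stochastic_methods_deterministic_given_seed(
        self, small_masked_matrix, fast_settings, method
    ):
        a = impute_matrix(small_masked_matrix, method, fast_settings)
        b = impute_matrix(small_masked_matrix, method, fast_settings)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("method", ["HM", "QRILC"])
    def test_left_censoring_orientation(self, small_masked_matrix, fast_settings, method):
        # left-censoring imputers only ever fill in low values
        out = impute_matrix(small_masked_matrix, method, fast_settings)
        miss = small_masked_matrix.isna().to_numpy()
        if method == "HM":
            medians = small_masked_matrix.median(axis=1).to_numpy()[:, None]
        else:
            medians = small_masked_matrix.median(axis=0).to_numpy()[None, :]
        assert (out.to_numpy()[miss] <= np.broadcast_to(medians, out.shape)[miss]).all()

    def test_unknown_method_rejected(self, small_masked_matrix):
        with pytest.raises(ValueError, match="unknown imputation method"):
            impute_matrix(small_masked_matrix, "MEAN")


class TestHalfMinimum:
    def test_half_of_smallest_observed(self):
        # raw values {4, 6, 8} -> missing imputed at raw 2.0 (log scale here)
        row = np.log([4.0, 6.0, 8.0, 4.0])
        m = _df([row, row])
        m.iloc[0, 3] = np.nan
        out = impute_half_minimum(m)
        assert out.iloc[0, 3] == pytest.approx(np.log(2.0))

    def test_identical_fill_for_all_cells_of_a_row(self):
        m = _df(np.log([[4, 6, 8, 5, 7]] * 2))
        m.iloc[0, [1, 3]] = np.nan
        out = impute_half_minimum(m)
        assert out.iloc[0, 1] == out.iloc[0, 3]

    def test_all_missing_row_is_an_error(self):
        m = _df([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="met1"):
            impute_half_minimum(m)


class TestKnn:
    def test_zero_distance_duplicate_copied_exactly(self):
        base = np.array([1.0, 5.0, 3.0, 2.0, 4.0])
        m = _df([base, base, base + 10.0])
        m.iloc[1, 2] = np.nan
        out = impute_knn(m, ImputerSettings(knn_k=1))
        assert out.iloc[1, 2] == base[2]

    def test_inverse_distance_weighting_arithmetic(self):
        # two neighbours valued 10 and 20 at distances 1 and 3:
        # (10/1 + 20/3) / (1/1 + 1/3) = 12.5
        target = np.array([0.0, 0.0, np.nan])
        near = np.array([1.0, 1.0, 10.0])     # rms distance 1 on shared cols
        far = np.array([3.0, -3.0, 20.0])     # rms distance 3
        m = _df([target, near, far])
        out = impute_knn(m, ImputerSettings(knn_k=2))
        assert out.iloc[0, 2] == pytest.approx(12.5)

    def test_row_past_missingness_cap_uses_column_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 10))
        x[0, :9] = np.nan  # 90% missing > 80% cap
        m = _df(x)
        out = impute_knn(m, ImputerSettings(knn_k=2))
        col_means = np.nanmean(x, axis=0)
        np.testing.assert_allclose(out.to_numpy()[0, :9], col_means[:9])

    def test_subject_orientation_switch(self, small_masked_matrix):
        out = impute_knn(small_masked_matrix, ImputerSettings(knn_orientation="subjects"))
        assert not out.isna().any().any()

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            ImputerSettings(knn_k=0)


class TestRandomForest:
    def test_linear_relation_recovered(self):
        # y = 2x exactly; most imputed y-cells should land within 10% of 2x
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 10, 200)
        y = 2 * x
        m = _df(np.vstack([x, y]))
        missing_cols = rng.choice(200, 40, replace=False)
        m.iloc[1, missing_cols] = np.nan
        out = impute_random_forest(m, ImputerSettings(rf_trees=50, rf_max_iter=5, seed=1))
        imputed = out.to_numpy()[1, missing_cols]
        truth = 2 * x[missing_cols]
        assert (np.abs(imputed - truth) / truth < 0.10).mean() >= 0.95

    def test_constant_row_imputed_to_constant(self):
        m = _df([[3.0] * 8, list(range(8))])
        m.iloc[0, [2, 5]] = np.nan
        out = impute_random_forest(m, ImputerSettings(rf_trees=10, seed=0))
        assert (out.iloc[0] == 3.0).all()

    def test_single_variable_rejected(self):
        # one metabolite row = a single variable: no predictors exist
        with pytest.raises(ValueError, match="2 variables"):
            impute_random_forest(_df([[1.0, np.nan, 3.0]]))


class TestEmNormal:
    def test_complete_data_matches_closed_form_mle(self):
        rng = np.random.default_rng(7)
        x = rng.multivariate_normal([0, 1, -1], np.eye(3) + 0.5, size=150)
        fit = fit_em_normal(x, ridge=0.0)
        np.testing.assert_allclose(fit.mean, x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(fit.cov, np.cov(x, rowvar=False, ddof=0), atol=1e-8)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(8)
        x = rng.multivariate_normal([0, 0, 0], [[1, .6, .2], [.6, 1, .4], [.2, .4, 1]], 300)
        x[rng.random(x.shape) < 0.25] = np.nan
        fit = fit_em_normal(x, ridge=0.0)
        steps = np.diff(fit.loglik_trace)
        assert (steps > -1e-6).all()

    def test_correlation_recovery_under_mcar(self):
        # r = 0.6 with 30% MCAR on one coordinate, n = 1000, 20 seeds
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=1000)
            x[rng.random(1000) < 0.3, 1] = np.nan
            fit = fit_em_normal(x, ridge=0.0)
            r_hat = fit.cov[0, 1] / np.sqrt(fit.cov[0, 0] * fit.cov[1, 1])
            errs.append(r_hat - 0.6)
        assert abs(np.mean(errs)) < 0.08

    def test_ridge_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            fit_em_normal(np.zeros((5, 2)), ridge=-1.0)


class TestEmb:
    def test_constant_variables_imputed_to_constant(self):
        x = np.tile(np.array([[2.0], [5.0], [7.0]]), (1, 10))
        m = _df(x)
        m.iloc[0, [1, 4]] = np.nan
        out = impute_emb(m, ImputerSettings(seed=2))
        assert np.allclose(out.iloc[0], 2.0, atol=1e-3)

    def test_conditional_draws_track_the_regression_line(self):
        # strongly correlated pair: imputed values should correlate with truth
        rng = np.random.default_rng(5)
        n = 1000
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=n)
        truth = z[:, 1].copy()
        holes = rng.random(n) < 0.2
        m = _df(z.T)
        m.iloc[1, holes] = np.nan
        out = impute_emb(m, ImputerSettings(seed=3))
        r = np.corrcoef(truth[holes], out.to_numpy()[1, holes])[0, 1]
        assert r > 0.6


class TestQrilc:
    def test_parameter_recovery_from_censored_column(self):
        # N(5, 1), n = 500, lowest 30% censored, 20 seeds
        mus, sigmas = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            full = np.sort(rng.normal(5, 1, 500))
            observed = full[150:]
            fit = fit_censored_column(observed, 0.30)
            mus.append(fit.mu)
            sigmas.append(fit.sigma)
        assert abs(np.mean(mus) - 5) < 0.15
        assert abs(np.mean(sigmas) - 1) < 0.15

    def test_imputed_values_below_censoring_threshold(self, small_masked_matrix):
        out = impute_qrilc(small_masked_matrix, ImputerSettings(seed=4))
        x = small_masked_matrix.to_numpy()
        for j in range(x.shape[1]):
            mj = np.isnan(x[:, j])
            if not mj.any() or (~mj).sum() < 5:
                continue
            fit = fit_censored_column(x[~mj, j], mj.mean())
            assert (out.to_numpy()[mj, j] <= fit.censoring_threshold + 1e-9).all()

    def test_column_without_missing_untouched(self):
        rng = np.random.default_rng(6)
        x = rng.normal(5, 1, size=(30, 4))
        m = _df(x)
        m.iloc[:10, 0] = np.nan
        out = impute_qrilc(m, ImputerSettings(seed=1))
        np.testing.assert_array_equal(out.to_numpy()[:, 1:], x[:, 1:])

    def test_sparse_column_falls_back_to_half_minimum(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5, 1, size=(8, 3))
        m = _df(x)
        m.iloc[:5, 0] = np.nan  # 3 observed < 5 -> fallback
        with pytest.warns(RuntimeWarning, match="half-minimum"):
            out = impute_qrilc(m, ImputerSettings(seed=1))
        expected = np.nanmin(m.to_numpy(), axis=1)[:5] - np.log(2)
        np.testing.assert_allclose(out.to_numpy()[:5, 0], expected)
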