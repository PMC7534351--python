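"""OLS fitting, diagnostics, leave-one-out validation, and interval bands.

Independent oracles: hand-derived closed forms, explicit normal equations,
statsmodels OLS, and an explicit scikit-learn LeaveOneOut refit loop.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.model_selection import LeaveOneOut

import qsarforge as qf
from qsarforge.dataset_io import DatasetError
from qsarforge.mlr_core import RankDeficiencyError, design_matrix
from conftest import random_dataset


def make_ds(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return qf.QsarDataset(
        [f"c{i}" for i in range(len(X))],
        [f"D{j + 1}" for j in range(X.shape[1])],
        X, np.asarray(y, dtype=float))


class TestFitOls:
    def test_hand_derived_simple_regression(self):
        # {(0,1),(1,3),(2,5)}: slope 2, intercept 1 by the normal equations
        ds = make_ds([[0.0], [1.0], [2.0]], [1.0, 3.0, 5.0])
        m = qf.fit_ols(ds)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_planted_model_recovered_exactly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
        m = qf.fit_ols(make_ds(X, y))
        assert m.coefficients == pytest.approx((2.0, -3.0), abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng)
        m = qf.fit_ols(ds)
        A = design_matrix(ds.X)
        beta = np.linalg.solve(A.T @ A, A.T @ ds.y)
        assert np.asarray((m.intercept, *m.coefficients)) == pytest.approx(beta, rel=1e-8)

    def test_rank_deficiency_names_offending_columns(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])  # D3 = 2*D1
        with pytest.raises(RankDeficiencyError) as err:
            qf.fit_ols(make_ds(X, np.zeros(10)))
        assert "D3" in err.value.columns or "D1" in err.value.columns

    def test_too_few_rows_rejected(self):
        with pytest.raises(DatasetError, match="n=3"):
            qf.fit_ols(make_ds(np.eye(3, 2), np.zeros(3)))


class TestGoodnessOfFit:
    def test_statsmodels_agreement_on_study_data(self, raf1_dataset, v600e_dataset):
        for ds in (raf1_dataset, v600e_dataset):
            m = qf.fit_ols(ds)
            st = qf.goodness_of_fit(m, ds)
            ref = sm.OLS(ds.y, sm.add_constant(ds.X)).fit()
            assert st.R2 == pytest.approx(ref.rsquared, rel=1e-10)
            assert st.F == pytest.approx(ref.fvalue, rel=1e-8)
            assert st.s == pytest.approx(np.sqrt(ref.mse_resid), rel=1e-10)

    def test_perfect_fit(self):
        X = np.arange(8.0).reshape(-1, 1)
        ds = make_ds(X, 2.0 * X[:, 0] + 1.0)
        st = qf.goodness_of_fit(qf.fit_ols(ds), ds)
        assert st.R2 == pytest.approx(1.0)
        assert st.RSS == pytest.approx(0.0, abs=1e-20)
        assert st.s == pytest.approx(0.0, abs=1e-10)

    def test_f_consistent_with_mean_squares(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng)
        m = qf.fit_ols(ds)
        st = qf.goodness_of_fit(m, ds)
        msr = (st.TSS - st.RSS) / ds.p
        mse = st.RSS / (ds.n - ds.p - 1)
        assert st.F == pytest.approx(msr / mse, rel=1e-10)

    def test_s_never_below_training_rmse(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ds = random_dataset(rng)
            st = qf.goodness_of_fit(qf.fit_ols(ds), ds)
            assert st.s >= st.RMSE_train

    def test_permutation_invariance(self, v600e_dataset):
        ds = v600e_dataset
        perm = np.random.default_rng(1).permutation(ds.n)
        shuffled = qf.QsarDataset(
            [ds.ids[i] for i in perm], ds.descriptor_names, ds.X[perm], ds.y[perm])
        a = qf.goodness_of_fit(qf.fit_ols(ds), ds)
        b = qf.goodness_of_fit(qf.fit_ols(shuffled), shuffled)
        assert a.R2 == pytest.approx(b.R2, rel=1e-12)
        assert a.F == pytest.approx(b.F, rel=1e-12)

    def test_nested_r2_monotonicity(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(20, 5))
        y = X[:, 0] - X[:, 1] + rng.normal(scale=0.5, size=20)
        r2 = []
        for k in range(1, 6):
            ds = make_ds(X[:, :k], y)
            r2.append(qf.goodness_of_fit(qf.fit_ols(ds), ds).R2)
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))


class TestPredict:
    def test_printed_coefficient_arithmetic(self):
        # 13.505 - 35.647*0.027 - 1.367*3.237 = 8.118 (3 dp)
        m = qf.MLRModel(("IW1", "FLEX"), (-35.647, -1.367), 13.505, n=9)
        val = qf.predict(m, [[0.027, 3.237]])[0]
        assert round(val, 3) == pytest.approx(8.118, abs=5e-4)

    def test_zero_row_returns_intercept(self):
        m = qf.MLRModel(("a", "b"), (2.0, 3.0), 4.5, n=9)
        assert qf.predict(m, [[0.0, 0.0]])[0] == 4.5

    def test_mapping_input_and_missing_descriptor(self):
        m = qf.MLRModel(("a", "b"), (1.0, 1.0), 0.0, n=9)
        out = qf.predict(m, {"b": [2.0], "a": [1.0]})
        assert out[0] == pytest.approx(3.0)
        with pytest.raises(DatasetError, match="missing descriptors"):
            qf.predict(m, {"a": [1.0]})


class TestLeaveOneOut:
    def test_shortcut_equals_explicit_refit(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            ds = random_dataset(rng)
            fast = qf.loo_cross_validate(ds, method="hat")
            slow = qf.loo_cross_validate(ds, method="refit")
            assert fast.PRESS == pytest.approx(slow.PRESS, rel=1e-10)
            np.testing.assert_allclose(
                fast.heldout_predictions, slow.heldout_predictions, rtol=1e-9, atol=1e-12)

    def test_sklearn_loo_oracle(self, raf1_dataset):
        ds = raf1_dataset
        ours = qf.loo_cross_validate(ds)
        press = 0.0
        for train, test in LeaveOneOut().split(ds.X):
            A = design_matrix(ds.X[train])
            beta, *_ = np.linalg.lstsq(A, ds.y[train], rcond=None)
            pred = design_matrix(ds.X[test]) @ beta
            press += float(((ds.y[test] - pred) ** 2).sum())
        assert ours.PRESS == pytest.approx(press, rel=1e-10)

    def test_noiseless_data_gives_q2_one(self):
        X = np.linspace(0, 1, 10).reshape(-1, 1)
        ds = make_ds(X, 3.0 * X[:, 0] + 2.0)
        assert qf.loo_cross_validate(ds).Q2 == pytest.approx(1.0, abs=1e-10)

    def test_q2_below_r2_and_press_above_rss(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            ds = random_dataset(rng)
            st = qf.goodness_of_fit(qf.fit_ols(ds), ds)
            loo = qf.loo_cross_validate(ds)
            assert loo.Q2 <= st.R2 + 1e-12
            assert loo.PRESS >= st.RSS - 1e-12

    def test_insufficient_folds_rejected(self):
        ds = make_ds(np.arange(3.0).reshape(-1, 1), [0.0, 1.0, 2.0])
        with pytest.raises(DatasetError, match="n >= p \\+ 3"):
            qf.loo_cross_validate(ds)


class TestPredictionBand:
    def test_prediction_wider_than_confidence_everywhere(self, v600e_dataset):
        m = qf.fit_ols(v600e_dataset)
        band = qf.prediction_band(m, v600e_dataset, level=0.95)
        assert np.all(band["prediction_halfwidth"] > band["confidence_halfwidth"])
        assert not band["zero_width_warning"]

    def test_halfwidths_scale_by_t_quantile_ratio(self, raf1_dataset):
        m = qf.fit_ols(raf1_dataset)
        b95 = qf.prediction_band(m, raf1_dataset, level=0.95)
        b50 = qf.prediction_band(m, raf1_dataset, level=0.50)
        dof = raf1_dataset.n - m.p - 1
        ratio = sps.t.ppf(0.975, dof) / sps.t.ppf(0.75, dof)
        np.testing.assert_allclose(
            b95["confidence_halfwidth"] / b50["confidence_halfwidth"], ratio, rtol=1e-10)

    def test_confidence_limit_at_mean_approaches_ts_over_sqrt_n(self):
        rng = np.random.default_rng(5)
        n = 4000
        X = rng.normal(size=(n, 1))
        y = 1.0 + X[:, 0] + rng.normal(scale=0.5, size=n)
        ds = make_ds(X, y)
        m = qf.fit_ols(ds)
        st = qf.goodness_of_fit(m, ds)
        band = qf.prediction_band(m, ds, rows=np.array([[X[:, 0].mean()]]))
        t = sps.t.ppf(0.975, n - 2)
        assert band["confidence_halfwidth"][0] == pytest.approx(t * st.s / np.sqrt(n), rel=0.05)

    def test_zero_residual_fit_flags_zero_width(self):
        X = np.arange(8.0).reshape(-1, 1)
        ds = make_ds(X, 2.0 * X[:, 0] + 1.0)
        m = qf.fit_ols(ds)
        with pytest.warns(UserWarning, match="zero width"):
            band = qf.prediction_band(m, ds)
        assert band["zero_width_warning"]
        np.testing.assert_allclose(band["confidence_halfwidth"], 0.0, atol=1e-8)

    def test_invalid_level_rejected(self, raf1_dataset):
        m = qf.fit_ols(raf1_dataset)
        with pytest.raises(ValueError):
            qf.prediction_band(m, raf1_dataset, level=1.5)
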