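"""NIPALS PLS1: exactness limits, merit figures, factor selection, and
agreement with independent reference implementations."""

import numpy as np
import pytest

from nirqc.design import hgc_formulation, make_blend_design
from nirqc.pls import (
    RankDeficiencyError,
    correlation,
    cross_validate,
    error_interval,
    fit_pls1,
    predict,
    rmse,
    rmsec,
    rmsep,
    venetian_blinds,
)
from nirqc.preprocess import paper_plan
from nirqc.simulate import NoiseModel, default_grid, default_library, simulate_set


def _synthetic_linear(n=30, p=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFitPredict:
    def test_one_factor_exact_on_rank_one_signal(self):
        """y exactly linear in a single spectral component: one latent factor
        recovers it to numerical precision."""
        rng = np.random.default_rng(1)
        direction = rng.normal(size=50)
        t = rng.normal(size=40)
        X = np.outer(t, direction)
        y = 3.0 + 2.0 * t
        model = fit_pls1(X, y, 1)
        assert model.rmsec < 1e-8

    def test_full_rank_equals_ols(self):
        """At full rank PLS1 spans the feature space, so predictions coincide
        with the ordinary least-squares solution."""
        X, y = _synthetic_linear(n=40, p=6, noise=0.5, seed=2)
        model = fit_pls1(X, y, 6)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        yhat_ols = Xc @ beta + y.mean()
        assert predict(model, X) == pytest.approx(yhat_ols, abs=1e-6)

    def test_permutation_invariance(self):
        X, y = _synthetic_linear(seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(y))
        m1 = fit_pls1(X, y, 3)
        m2 = fit_pls1(X[perm], y[perm], 3)
        assert m1.coef == pytest.approx(m2.coef, abs=1e-10)

    def test_mean_spectrum_predicts_mean_response(self):
        X, y = _synthetic_linear(seed=5)
        model = fit_pls1(X, y, 3)
        assert predict(model, X.mean(axis=0)) == pytest.approx(y.mean())

    def test_score_orthogonality(self):
        X, y = _synthetic_linear(n=50, p=20, noise=1.0, seed=6)
        model = fit_pls1(X, y, 5)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_rank_deficiency_raises(self):
        X = np.zeros((10, 5))
        with pytest.raises(RankDeficiencyError):
            fit_pls1(X, np.arange(10.0), 2)
        with pytest.raises(RankDeficiencyError):
            fit_pls1(np.random.default_rng(0).normal(size=(3, 5)), np.ones(3), 3)

    def test_matches_reference_pls_implementation(self):
        """Cross-check against scikit-learn's PLS regression (oracle only)."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _synthetic_linear(n=60, p=15, noise=0.3, seed=7)
        for a in (1, 3, 5):
            model = fit_pls1(X, y, a)
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(
                X, y.reshape(-1, 1)
            )
            assert predict(model, X) == pytest.approx(
                ref.predict(X).ravel(), abs=1e-6
            )

    def test_rmsec_non_increasing_in_factor_count(self):
        X, y = _synthetic_linear(n=40, p=12, noise=1.0, seed=8)
        errs = [fit_pls1(X, y, a).rmsec for a in range(1, 9)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


class TestMeritFigures:
    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [1.0, -1.0]) == pytest.approx(1.0)

    def test_rmse_independent_oracle(self):
        rng = np.random.default_rng(9)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        expected = float(np.sqrt(sum((a - b) ** 2 for a, b in zip(yhat, y)) / 50))
        assert rmse(y, yhat) == pytest.approx(expected)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_correlation_limits(self):
        y = np.arange(10.0)
        assert correlation(y, y) == pytest.approx(1.0)
        assert correlation(y, -y) == pytest.approx(-1.0)

    def test_correlation_textbook_table(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.8])
        sxy = np.sum((y - y.mean()) * (yhat - yhat.mean()))
        expected = sxy / np.sqrt(
            np.sum((y - y.mean()) ** 2) * np.sum((yhat - yhat.mean()) ** 2)
        )
        assert correlation(y, yhat) == pytest.approx(expected)

    def test_correlation_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(5), np.arange(5.0))

    def test_error_interval(self):
        assert error_interval([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)
        y = np.zeros(3)
        yhat = np.array([-2.3, 1.0, 2.9])
        assert error_interval(y, yhat) == pytest.approx((-2.3, 2.9))
        rng = np.random.default_rng(10)
        y, yhat = rng.normal(size=30), rng.normal(size=30)
        res = sorted(yhat - y)
        assert error_interval(y, yhat) == pytest.approx((res[0], res[-1]))


class TestCrossValidation:
    def test_venetian_blinds_stratified(self):
        strata = np.repeat(np.arange(9), 6)
        folds = venetian_blinds(54, 6, strata)
        assert sum(f.size for f in folds) == 54
        for f in folds:
            assert np.array_equal(np.sort(strata[f]), np.arange(9))

    def test_noise_free_two_component_selects_two_factors(self):
        rng = np.random.default_rng(11)
        C = rng.uniform(0.2, 0.8, size=(30, 2))
        S = rng.normal(size=(2, 40))
        X = C @ S
        y = C[:, 0]
        cv = cross_validate(X, y, max_factors=5, n_splits=5)
        assert cv.n_factors == 2
        assert cv.rmsecv[1] < 1e-8

    def test_single_factor_trivially_selected(self):
        X, y = _synthetic_linear(seed=12)
        cv = cross_validate(X, y, max_factors=1, n_splits=5)
        assert cv.n_factors == 1
        assert cv.rmsecv.size == 1

    def test_loo_fold_count(self):
        X, y = _synthetic_linear(n=15, seed=13)
        cv = cross_validate(X, y, max_factors=2, scheme="loo")
        assert cv.scheme == "loo"
        assert cv.rmsecv.size == 2

    def test_unknown_scheme_rejected(self):
        X, y = _synthetic_linear(seed=14)
        with pytest.raises(ValueError, match="scheme"):
            cross_validate(X, y, 2, scheme="bootstrap")


class TestOnSyntheticSpectra:
    def test_calibration_bias_below_one_percent(self, library, grid):
        """Default-noise 54-sample calibration predicts an independent
        27-sample validation set with mean absolute bias < 1% of label."""
        form = hgc_formulation()
        cal_d = make_blend_design(form, "AZ")
        val_d = make_blend_design(form, "AZ", total_mass=1026.82, replicates=3,
                                  role="validation")
        cal = simulate_set(cal_d, library, grid, NoiseModel(), 3, seed=20)
        val = simulate_set(val_d, library, grid, NoiseModel(), 3, seed=21)
        plan = paper_plan()
        model = fit_pls1(plan.fit_transform(cal), cal.meta["percent_AZ"], 5)
        yhat = predict(model, plan.transform(val))
        assert np.mean(np.abs(yhat - val.meta["percent_AZ"])) < 1.0

    def test_rmsec_usually_below_rmsep(self, library, grid):
        """Training error is optimistically biased: RMSEC < RMSEP in the
        majority of repeated simulated studies."""
        form = hgc_formulation()
        cal_d = make_blend_design(form, "AZ", replicates=3)
        val_d = make_blend_design(form, "AZ", total_mass=1026.82, replicates=2,
                                  role="validation")
        plan = paper_plan()
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cal = simulate_set(cal_d, library, grid, NoiseModel(), 3, 100 + seed)
            val = simulate_set(val_d, library, grid, NoiseModel(), 3, 900 + seed)
            F = plan.fit_transform(cal)
            y = cal.meta["percent_AZ"].to_numpy()
            model = fit_pls1(F, y, 5)
            ec = rmsec(model, F, y)
            ep = rmsep(model, plan.transform(val), val.meta["percent_AZ"].to_numpy())
            wins += ec < ep
        assert wins > n_seeds / 2
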