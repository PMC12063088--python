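import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npxspectrum.scadridge import (
    LambdaPath,
    PenaltySpec,
    ScadRidgeClassifier,
    binomial_deviance,
    cv_select_lambda,
    fit,
    fit_path,
    kkt_residual,
    lambda_max,
    penalty_value,
    predict_proba,
    prox_coord,
    standardize,
)


def scad_penalty_oracle(t, lam1, a):
    """Independent vectorized SCAD penalty (integrated from its derivative)."""
    t = np.abs(np.asarray(t, float))
    flat = lam1 * t
    quad = (2 * a * lam1 * t - t**2 - lam1**2) / (2 * (a - 1))
    const = lam1**2 * (a + 1) / 2
    return np.where(t <= lam1, flat, np.where(t <= a * lam1, quad, const))


def prox_grid_oracle(z, spec, step=1e-4):
    """1-D grid minimization of the scalar prox objective."""
    lim = 3 * abs(z) + 1.0
    grid = np.arange(-lim, lim + step, step)
    f = (
        0.5 * (grid - z) ** 2
        + scad_penalty_oracle(grid, spec.lam1, spec.a)
        + 0.5 * spec.lam2 * grid**2
    )
    return grid[np.argmin(f)]


def make_logistic_data(n=500, p=5, seed=0, effect=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = effect * np.array([1.0, -0.6, 0.8, 0.0, 0.4])[:p]
    eta = X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestPenaltySpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -0.1},
            {"lam": 1.0, "alpha": 1.5},
            {"lam": 1.0, "a": 2.0},
            {"lam": 1.0, "df_max": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            PenaltySpec(**kwargs)

    def test_split(self):
        s = PenaltySpec(lam=2.0, alpha=0.1)
        assert s.lam1 == pytest.approx(0.2)
        assert s.lam2 == pytest.approx(1.8)


class TestPenaltyValue:
    def test_zero_beta(self):
        assert penalty_value(np.zeros(5), PenaltySpec(lam=1.0)) == 0.0

    def test_zero_lambda(self):
        assert penalty_value(np.array([1.0, -2.0]), PenaltySpec(lam=0.0)) == 0.0

    def test_pure_ridge(self):
        beta = np.array([1.0, -2.0, 0.5])
        spec = PenaltySpec(lam=0.8, alpha=0.0)
        assert penalty_value(beta, spec) == pytest.approx(0.5 * 0.8 * (beta**2).sum())

    def test_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            beta = rng.normal(size=6)
            spec = PenaltySpec(lam=rng.uniform(0.01, 2), alpha=rng.uniform(0, 1))
            want = (
                scad_penalty_oracle(beta, spec.lam1, spec.a).sum()
                + 0.5 * spec.lam2 * (beta**2).sum()
            )
            assert penalty_value(beta, spec) == pytest.approx(want, abs=1e-12)


class TestProxCoord:
    def test_identity_at_lambda_zero(self):
        assert prox_coord(0.7, PenaltySpec(lam=0.0)) == pytest.approx(0.7)

    def test_soft_threshold_zone(self):
        assert prox_coord(0.1, PenaltySpec(lam=0.2, alpha=1.0)) == 0.0

    def test_middle_zone_hand_value(self):
        # ((a-1)|z| - a*lam1) / ((a-1)(1+lam2) - 1) with a=3.7, lam1=0.2
        got = prox_coord(0.5, PenaltySpec(lam=0.2, alpha=1.0, a=3.7))
        assert got == pytest.approx((2.7 * 0.5 - 0.74) / 1.7, abs=1e-12)
        assert got == pytest.approx(0.358823529, abs=1e-8)

    def test_no_shrinkage_zone(self):
        assert prox_coord(2.0, PenaltySpec(lam=0.2, alpha=1.0, a=3.7)) == pytest.approx(2.0)

    def test_continuity_in_z(self):
        spec = PenaltySpec(lam=0.5, alpha=0.4)
        zs = np.linspace(-3, 3, 2001)
        vals = np.array([prox_coord(z, spec) for z in zs])
        assert np.abs(np.diff(vals)).max() < 0.02

    @settings(max_examples=300, deadline=None)
    @given(
        z=st.floats(-4, 4),
        lam=st.floats(0.001, 2),
        alpha=st.floats(0, 1),
        a=st.floats(2.1, 6),
    )
    def test_matches_grid_oracle(self, z, lam, alpha, a):
        spec = PenaltySpec(lam=lam, alpha=alpha, a=a)
        got = prox_coord(z, spec)
        want = prox_grid_oracle(z, spec, step=1e-4)
        assert abs(got - want) < 1e-3


class TestFit:
    def test_requires_standardized(self):
        X, y = make_logistic_data()
        with pytest.raises(ValueError, match="standardized"):
            fit(X + 5.0, y, PenaltySpec(lam=0.1))

    def test_requires_both_classes(self):
        X, _ = make_logistic_data(n=20)
        Xs, _, _ = standardize(X)
        with pytest.raises(ValueError, match="both classes"):
            fit(Xs, np.ones(20), PenaltySpec(lam=0.1))

    def test_huge_lambda_null_model(self):
        X, y = make_logistic_data()
        Xs, _, _ = standardize(X)
        f = fit(Xs, y, PenaltySpec(lam=50.0))
        assert f.df == 0
        ybar = y.mean()
        assert f.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-4)

    def test_mle_limit(self):
        from scipy.optimize import minimize

        X, y = make_logistic_data(seed=1)
        Xs, _, _ = standardize(X)
        f = fit(Xs, y, PenaltySpec(lam=1e-8), tol=1e-9, max_iter=500)

        def nll(v):
            eta = v[0] + Xs @ v[1:]
            return np.mean(np.logaddexp(0, -(2 * y - 1) * eta))

        res = minimize(nll, np.zeros(Xs.shape[1] + 1), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.abs(f.beta - res.x[1:]).max() < 1e-3
        assert abs(f.intercept - res.x[0]) < 1e-3

    def test_ridge_limit_convex_oracle(self):
        from scipy.optimize import minimize

        X, y = make_logistic_data(seed=2)
        Xs, _, _ = standardize(X)
        lam = 0.5
        f = fit(Xs, y, PenaltySpec(lam=lam, alpha=0.0), tol=1e-10, max_iter=500)

        def obj(v):
            eta = v[0] + Xs @ v[1:]
            return np.mean(np.logaddexp(0, -(2 * y - 1) * eta)) + 0.5 * lam * (
                v[1:] @ v[1:]
            )

        res = minimize(obj, np.zeros(Xs.shape[1] + 1), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.abs(f.beta - res.x[1:]).max() < 1e-4
        assert abs(f.intercept - res.x[0]) < 1e-4

    def test_lasso_limit_matches_sklearn(self):
        from sklearn.linear_model import LogisticRegression

        X, y = make_logistic_data(seed=3)
        Xs, _, _ = standardize(X)
        lam = 0.05
        # alpha=1, a -> inf: SCAD collapses to the lasso for these magnitudes
        f = fit(Xs, y, PenaltySpec(lam=lam, alpha=1.0, a=1e6), tol=1e-10, max_iter=500)
        n = len(y)
        skl = LogisticRegression(
            C=1.0 / (n * lam), l1_ratio=1.0, solver="saga", tol=1e-10, max_iter=50000
        ).fit(Xs, y)
        assert np.abs(f.beta - skl.coef_[0]).max() < 1e-3

    def test_objective_monotone_and_kkt(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            n, p = 150, 12
            X = rng.normal(size=(n, p))
            beta = rng.normal(0, 1, p) * (rng.random(p) < 0.4)
            y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
            if y.min() == y.max():
                continue
            Xs, _, _ = standardize(X)
            spec = PenaltySpec(
                lam=rng.uniform(0.01, 0.3), alpha=rng.uniform(0, 1), df_max=p
            )
            f = fit(Xs, y, spec, tol=1e-9, max_iter=500)
            assert np.all(np.diff(f.objective_trace) <= 1e-10)
            assert kkt_residual(Xs, y, f) < 1e-6

    def test_scale_equivariance(self):
        X, y = make_logistic_data(seed=4)
        Xs1, _, _ = standardize(X)
        X2 = X.copy()
        X2[:, 0] *= 37.0
        Xs2, _, _ = standardize(X2)
        spec = PenaltySpec(lam=0.05)
        f1 = fit(Xs1, y, spec)
        f2 = fit(Xs2, y, spec)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-3, 0.1, 25), rng.normal(3, 0.1, 25)])
        X = np.column_stack([x, rng.normal(size=50)])
        y = (x > 0).astype(float)
        Xs, _, _ = standardize(X)
        f = fit(Xs, y, PenaltySpec(lam=1e-10), max_iter=2000)
        assert not f.converged

    def test_original_scale_backtransform(self):
        X, y = make_logistic_data(seed=5)
        Xs, c, s = standardize(X)
        f = fit(Xs, y, PenaltySpec(lam=0.05))
        f.center, f.scale = c, s
        b0, beta = f.original_scale()
        eta_std = f.intercept + Xs @ f.beta
        eta_orig = b0 + X @ beta
        assert np.allclose(eta_std, eta_orig, atol=1e-10)


class TestFitPath:
    def test_empty_at_lambda_max(self):
        X, y = make_logistic_data(seed=6)
        Xs, _, _ = standardize(X)
        path = fit_path(Xs, y, PenaltySpec(lam=1.0, alpha=0.1), n_lambda=10)
        assert path.fits[0].df == 0

    def test_lambdas_strictly_decreasing(self):
        X, y = make_logistic_data(seed=6)
        Xs, _, _ = standardize(X)
        path = fit_path(Xs, y, PenaltySpec(lam=1.0), n_lambda=20)
        assert np.all(np.diff(path.lambdas) < 0)

    def test_df_cap_semantics(self):
        X, y = make_logistic_data(seed=7, effect=2.0)
        Xs, _, _ = standardize(X)
        path = fit_path(Xs, y, PenaltySpec(lam=1.0, alpha=0.5, df_max=1), n_lambda=30)
        assert all(f.df <= 1 for f in path.fits)
        assert path.truncated_at is not None

    def test_df_mostly_monotone_in_lambda(self):
        violations, steps = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 15))
            beta = np.zeros(15)
            beta[:5] = rng.normal(0, 1.5, 5)
            y = (rng.random(120) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
            if y.min() == y.max():
                continue
            Xs, _, _ = standardize(X)
            path = fit_path(
                Xs, y, PenaltySpec(lam=1.0, alpha=0.3, df_max=15), n_lambda=30
            )
            dfs = [f.df for f in path.fits]
            d = np.diff(dfs)
            violations += int((d < 0).sum())
            steps += len(d)
        assert violations <= 0.05 * steps

    def test_warm_start_continuity(self):
        X, y = make_logistic_data(seed=8)
        Xs, _, _ = standardize(X)
        path = fit_path(Xs, y, PenaltySpec(lam=1.0), n_lambda=40)
        # consecutive solutions should move smoothly
        deltas = [
            np.abs(path.fits[i + 1].beta - path.fits[i].beta).max()
            for i in range(len(path.fits) - 1)
        ]
        assert max(deltas) < 0.5


class TestCvSelectLambda:
    def test_deterministic_given_seed(self):
        X, y = make_logistic_data(seed=10)
        Xs, _, _ = standardize(X)
        spec = PenaltySpec(lam=1.0)
        l1, _ = cv_select_lambda(Xs, y, spec, seed=3, n_lambda=20)
        l2, _ = cv_select_lambda(Xs, y, spec, seed=3, n_lambda=20)
        assert l1 == l2

    def test_pure_noise_prefers_large_lambda(self):
        big = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 10))
            y = (rng.random(100) < 0.5).astype(float)
            Xs, _, _ = standardize(X)
            spec = PenaltySpec(lam=1.0, alpha=0.5)
            lam_star, curve = cv_select_lambda(Xs, y, spec, seed=seed, n_lambda=25)
            # selected lambda in the top (largest) third of the grid
            big += lam_star >= np.quantile(curve[:, 0], 2 / 3)
        assert big >= 0.8 * n_seeds

    def test_strong_predictor_selected(self):
        hit = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(150, 8))
            y = (rng.random(150) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(float)
            Xs, _, _ = standardize(X)
            spec = PenaltySpec(lam=1.0, alpha=0.5)
            lam_star, _ = cv_select_lambda(Xs, y, spec, seed=seed, n_lambda=25)
            f = fit(Xs, y, PenaltySpec(lam=lam_star, alpha=0.5))
            hit += 0 in f.active_set
        assert hit >= 0.95 * n_seeds

    def test_too_few_samples(self):
        X, y = make_logistic_data(n=8)
        Xs, _, _ = standardize(X)
        with pytest.raises(ValueError):
            cv_select_lambda(Xs, y, PenaltySpec(lam=1.0), k=5)


class TestPredictProba:
    def test_null_model_half(self):
        f = fit_from_coefs(np.zeros(3), 0.0)
        p = predict_proba(f, np.random.default_rng(0).normal(size=(5, 3)))
        assert np.allclose(p, 0.5)

    def test_at_training_mean(self):
        f = fit_from_coefs(np.array([1.0, -1.0]), 0.3)
        p = predict_proba(f, np.zeros((1, 2)))
        assert p[0] == pytest.approx(1 / (1 + np.exp(-0.3)))

    def test_monotone_single_predictor(self):
        f = fit_from_coefs(np.array([2.0]), 0.0)
        xs = np.linspace(-2, 2, 9).reshape(-1, 1)
        p = predict_proba(f, xs)
        assert np.all(np.diff(p) > 0)

    def test_dimension_mismatch(self):
        f = fit_from_coefs(np.array([1.0, 2.0]), 0.0)
        with pytest.raises(ValueError):
            predict_proba(f, np.zeros((3, 5)))


def fit_from_coefs(beta, intercept):
    from npxspectrum.scadridge import LogisticFit

    return LogisticFit(
        intercept=intercept,
        beta=np.asarray(beta, float),
        active_set=np.flatnonzero(beta),
        n_iter=0,
        converged=True,
        objective=0.0,
        spec=PenaltySpec(lam=0.0),
    )


class TestClassifierWrapper:
    def test_end_to_end(self):
        X, y = make_logistic_data(n=200, seed=11, effect=1.5)
        clf = ScadRidgeClassifier(n_lambda=20, seed=0).fit(X, y)
        p = clf.predict_proba(X)
        assert p.shape == (200, 2)
        assert np.allclose(p.sum(axis=1), 1.0)
        from npxspectrum.metrics import auc

        assert auc(p[:, 1], y) > 0.75

    def test_serialization_roundtrip(self):
        X, y = make_logistic_data(n=120, seed=12)
        clf = ScadRidgeClassifier(n_lambda=15, seed=1).fit(X, y)
        d = clf.fit_.to_dict()
        assert d["spec"]["alpha"] == 0.1
        assert len(d["beta"]) == X.shape[1]
        assert d["center"] is not None
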