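"""Penalized logistic regression with a mixed SCAD + L2 (ridge) penalty.

The penalty on a coefficient vector beta is::

    P(beta) = sum_j [ p_scad(|beta_j|; lam1, a) + (lam2 / 2) * beta_j**2 ]

with lam1 = alpha * lam (SCAD share) and lam2 = (1 - alpha) * lam (ridge
share). alpha = 0 is pure ridge; alpha = 1 with large ``a`` behaves like
the lasso. p_scad is the standard three-zone SCAD: derivative lam1 for
t <= lam1, (a*lam1 - t)/(a - 1) for lam1 < t <= a*lam1, and 0 beyond.

The solver is IRLS-wrapped coordinate descent with warm starts along a
descending lambda path and a cap (``df_max``) on the number of selected
variables enforced by path truncation. Each scalar update solves the
weighted one-dimensional subproblem exactly by candidate enumeration over
the piecewise-quadratic zones, which stays correct even where the
nonconvex middle zone loses positive curvature.

The kernel compiles with numba when available and runs as plain Python
otherwise (identical numerics, slower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PenaltySpec",
    "LogisticFit",
    "LambdaPath",
    "penalty_value",
    "prox_coord",
    "standardize",
    "fit",
    "fit_path",
    "cv_select_lambda",
    "predict_proba",
    "kkt_residual",
    "binomial_deviance",
    "ScadRidgeClassifier",
]

_P_EPS = 1e-10


@dataclass(frozen=True)
class PenaltySpec:
    """Hyperparameters of the SCAD + ridge penalty."""

    lam: float
    alpha: float = 0.1
    a: float = 3.7
    df_max: int = 28

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.a <= 2.0:
            raise ValueError("SCAD shape parameter a must be > 2")
        if self.df_max < 1:
            raise ValueError("df_max must be >= 1")

    @property
    def lam1(self) -> float:
        return self.alpha * self.lam

    @property
    def lam2(self) -> float:
        return (1.0 - self.alpha) * self.lam


@dataclass
class LogisticFit:
    """A fitted penalized logistic model on the standardized-predictor scale."""

    intercept: float
    beta: np.ndarray
    active_set: np.ndarray
    n_iter: int
    converged: bool
    objective: float
    spec: PenaltySpec
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    objective_trace: np.ndarray | None = None

    @property
    def df(self) -> int:
        return int(len(self.active_set))

    def original_scale(self) -> tuple[float, np.ndarray]:
        """Back-transform (intercept, beta) to the raw predictor scale."""
        if self.center is None or self.scale is None:
            raise ValueError("fit carries no standardization parameters")
        beta_orig = self.beta / self.scale
        b0 = self.intercept - float(np.dot(beta_orig, self.center))
        return b0, beta_orig

    def to_dict(self) -> dict:
        d = {
            "intercept": self.intercept,
            "beta": self.beta.tolist(),
            "active_set": self.active_set.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "objective": self.objective,
            "spec": {
                "lam": self.spec.lam,
                "alpha": self.spec.alpha,
                "a": self.spec.a,
                "df_max": self.spec.df_max,
            },
        }
        if self.center is not None:
            d["center"] = self.center.tolist()
            d["scale"] = self.scale.tolist()
        return d


@dataclass
class LambdaPath:
    """Warm-started fits along a strictly decreasing lambda sequence."""

    lambdas: np.ndarray
    fits: list[LogisticFit]
    truncated_at: int | None = None


# ---------------------------------------------------------------------------
# penalty and scalar prox
# ---------------------------------------------------------------------------

def _scad_pen_scalar(t: float, lam1: float, a: float) -> float:
    """SCAD penalty value at t >= 0."""
    if t <= lam1:
        return lam1 * t
    if t <= a * lam1:
        return (2.0 * a * lam1 * t - t * t - lam1 * lam1) / (2.0 * (a - 1.0))
    return lam1 * lam1 * (a + 1.0) / 2.0


def _prox_w_scalar(u: float, v: float, lam1: float, lam2: float, a: float) -> float:
    """Exact argmin over beta of (v/2)b^2 - u*b + p_scad(|b|) + (lam2/2)b^2.

    Candidate enumeration: stationary points of each quadratic zone
    (clipped to the zone) plus the breakpoints 0, lam1, a*lam1. Exact for
    any v > 0, including where the middle zone is nonconvex.
    """
    if lam1 == 0.0 and lam2 == 0.0:
        return u / v
    s = 1.0 if u >= 0.0 else -1.0
    au = abs(u)
    vq = v + lam2
    # zone stationary points, clipped into their zones
    c0 = 0.0
    c1 = (au - lam1) / vq
    if c1 < 0.0:
        c1 = 0.0
    elif c1 > lam1:
        c1 = lam1
    den = (a - 1.0) * vq - 1.0
    if den > 1e-12:
        c2 = ((a - 1.0) * au - a * lam1) / den
        if c2 < lam1:
            c2 = lam1
        elif c2 > a * lam1:
            c2 = a * lam1
    else:
        c2 = lam1  # concave piece: minimum at a zone boundary
    c3 = au / vq
    if c3 < a * lam1:
        c3 = a * lam1
    best_t = 0.0
    best_f = 0.0
    for t in (c0, c1, c2, lam1, c3, a * lam1):
        f = 0.5 * vq * t * t - au * t + _scad_pen_scalar(t, lam1, a)
        if f < best_f - 1e-15:
            best_f = f
            best_t = t
    return s * best_t


def _irls_cd(X, X2, y, lam1, lam2, a, beta, b0, tol, max_iter, inner_max):
    """IRLS + coordinate descent with monotone backtracking.

    Mutates nothing; returns (beta, b0, n_iter, converged, objective).
    """
    n, p = X.shape
    beta = beta.copy()
    eta = b0 + X @ beta
    obj = _objective_arrays(X, y, beta, b0, lam1, lam2, a)
    trace = np.empty(max_iter + 1)
    trace[0] = obj
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta_prev = beta.copy()
        b0_prev = b0
        # quadratic approximation at current eta
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = pr * (1.0 - pr)
        for i in range(n):
            if w[i] < 1e-5:
                w[i] = 1e-5
        z = eta + (y - pr) / w
        r = z - eta
        v = (w @ X2) / n
        wsum = w.sum()
        # majorize: lift per-coordinate curvature so the scalar subproblem
        # with the nonconvex SCAD zone stays convex ((a-1)(v+lam2) > 1);
        # the extra curvature cancels at fixed points, keeping KKT exact
        veff = v.copy()
        if lam1 > 0.0:
            vmin = 1.0 / (a - 1.0) - lam2 + 1e-4
            for j in range(p):
                if veff[j] < vmin:
                    veff[j] = vmin
        # CD on the weighted least-squares surrogate: full sweeps alternate
        # with cheap sweeps over the current active set (glmnet-style)
        for _ in range(inner_max):
            delta = 0.0
            shift = (w @ r) / wsum
            b0 += shift
            r -= shift
            if abs(shift) > delta:
                delta = abs(shift)
            for j in range(p):
                bj = beta[j]
                u = (w * X[:, j]) @ r / n + veff[j] * bj
                bnew = _prox_w_scalar(u, veff[j], lam1, lam2, a)
                if bnew != bj:
                    r += X[:, j] * (bj - bnew)
                    beta[j] = bnew
                    if abs(bnew - bj) > delta:
                        delta = abs(bnew - bj)
            if delta < tol:
                break
            for _ in range(inner_max):
                d2 = 0.0
                shift = (w @ r) / wsum
                b0 += shift
                r -= shift
                if abs(shift) > d2:
                    d2 = abs(shift)
                for j in range(p):
                    bj = beta[j]
                    if bj == 0.0:
                        continue
                    u = (w * X[:, j]) @ r / n + veff[j] * bj
                    bnew = _prox_w_scalar(u, veff[j], lam1, lam2, a)
                    if bnew != bj:
                        r += X[:, j] * (bj - bnew)
                        beta[j] = bnew
                        if abs(bnew - bj) > d2:
                            d2 = abs(bnew - bj)
                if d2 < tol:
                    break
        # backtrack toward the previous iterate if the true objective rose
        eta = b0 + X @ beta
        new_obj = _objective_arrays(X, y, beta, b0, lam1, lam2, a)
        step = 1.0
        while new_obj > obj + 1e-12 and step > 1e-8:
            step *= 0.5
            beta = beta_prev + step * (beta - beta_prev)
            b0 = b0_prev + step * (b0 - b0_prev)
            eta = b0 + X @ beta
            new_obj = _objective_arrays(X, y, beta, b0, lam1, lam2, a)
        if new_obj > obj + 1e-12:
            beta = beta_prev
            b0 = b0_prev
            eta = b0 + X @ beta
            new_obj = obj
        max_change = abs(b0 - b0_prev)
        for j in range(p):
            c = abs(beta[j] - beta_prev[j])
            if c > max_change:
                max_change = c
        obj = new_obj
        trace[it] = obj
        if max_change < tol:
            converged = True
            break
    return beta, b0, it, converged, obj, trace[: it + 1]


def _objective_arrays(X, y, beta, b0, lam1, lam2, a):
    """Penalized mean negative log-likelihood."""
    eta = b0 + X @ beta
    # log(1 + exp(-(2y-1)*eta)), stable
    m = (2.0 * y - 1.0) * eta
    loss = 0.0
    for i in range(m.shape[0]):
        t = -m[i]
        if t > 35.0:
            loss += t
        else:
            loss += math.log1p(math.exp(t))
    loss /= m.shape[0]
    pen = 0.0
    for j in range(beta.shape[0]):
        t = abs(beta[j])
        pen += _scad_pen_scalar(t, lam1, a) + 0.5 * lam2 * t * t
    return loss + pen


# optional numba acceleration; numerics identical either way
try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _scad_pen_scalar = _njit(cache=True)(_scad_pen_scalar)
    _prox_w_scalar = _njit(cache=True)(_prox_w_scalar)
    _objective_arrays = _njit(cache=True)(_objective_arrays)
    _irls_cd = _njit(cache=True)(_irls_cd)
except Exception:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def penalty_value(beta: np.ndarray, spec: PenaltySpec) -> float:
    """Total penalty P(beta) for the given spec."""
    beta = np.asarray(beta, float)
    tot = 0.0
    for t in np.abs(beta):
        tot += _scad_pen_scalar(float(t), spec.lam1, spec.a) + 0.5 * spec.lam2 * t * t
    return float(tot)


def prox_coord(z: float, spec: PenaltySpec) -> float:
    """Solve argmin_b 0.5*(b - z)^2 + p_scad(|b|; lam1, a) + (lam2/2)*b^2."""
    return float(_prox_w_scalar(float(z), 1.0, spec.lam1, spec.lam2, spec.a))


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize X; returns (X_std, center, scale).

    Scale uses the population (ddof=0) standard deviation. Constant
    columns raise.
    """
    X = np.asarray(X, float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale <= 0):
        bad = np.flatnonzero(scale <= 0)
        raise ValueError(f"constant predictor columns: {bad.tolist()}")
    return (X - center) / scale, center, scale


def _check_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Fortran order: the solver walks columns
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    mu = np.abs(X.mean(axis=0)).max()
    sd = X.std(axis=0)
    if mu > 1e-6 or np.abs(sd - 1.0).max() > 1e-3:
        raise ValueError("X must be column-standardized (mean 0, sd 1)")
    return X, y


def fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    init: tuple[float, np.ndarray] | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> LogisticFit:
    """Fit the penalized logistic model on standardized predictors.

    The intercept is never penalized. Divergent fits (perfect separation
    at vanishing penalty) are returned flagged non-converged.
    """
    X, y = _check_inputs(X, y)
    return _fit_core(X, X * X, y, spec, init, tol, max_iter)


def _fit_core(
    X: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    init: tuple[float, np.ndarray] | None,
    tol: float,
    max_iter: int,
) -> LogisticFit:
    """Solver entry without revalidation; X, X2 already prepared."""
    n, p = X.shape
    if init is None:
        ybar = y.mean()
        b0 = float(np.log(ybar / (1.0 - ybar)))
        beta0 = np.zeros(p)
    else:
        b0 = float(init[0])
        beta0 = np.asarray(init[1], float).copy()
    beta, b0, n_iter, converged, obj, trace = _irls_cd(
        X, X2, y, spec.lam1, spec.lam2, spec.a, beta0, b0, tol, max_iter, 1000
    )
    if np.abs(beta).max(initial=0.0) > 1e4 or abs(b0) > 1e4:
        converged = False
    active = np.flatnonzero(beta != 0.0)
    return LogisticFit(
        intercept=float(b0),
        beta=np.asarray(beta),
        active_set=active,
        n_iter=int(n_iter),
        converged=bool(converged),
        objective=float(obj),
        spec=spec,
        objective_trace=np.asarray(trace),
    )


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which the active set is empty."""
    n = X.shape[0]
    score = X.T @ (y - y.mean())
    return float(np.abs(score).max() / (n * max(alpha, 0.001)))


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    spec_template: PenaltySpec,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 200,
    lambdas: np.ndarray | None = None,
    enforce_df_max: bool = True,
) -> LambdaPath:
    """Warm-started fits along a descending log-spaced lambda grid.

    The path stops at the first lambda whose active set exceeds
    ``spec_template.df_max``; that fit is discarded and its index recorded.
    """
    X, y = _check_inputs(X, y)
    if lambdas is None:
        lmax = lambda_max(X, y, spec_template.alpha)
        lambdas = np.exp(
            np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio), n_lambda)
        )
    lambdas = np.asarray(lambdas, float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda sequence must be strictly decreasing")
    fits: list[LogisticFit] = []
    truncated_at = None
    init = None
    X2 = X * X
    for idx, lam in enumerate(lambdas):
        spec = replace(spec_template, lam=float(lam))
        f = _fit_core(X, X2, y, spec, init=init, tol=tol, max_iter=max_iter)
        if enforce_df_max and f.df > spec_template.df_max:
            truncated_at = idx
            break
        fits.append(f)
        init = (f.intercept, f.beta)
    return LambdaPath(lambdas=lambdas[: len(fits)], fits=fits, truncated_at=truncated_at)


def predict_proba(fit_: LogisticFit, X_new: np.ndarray) -> np.ndarray:
    """Predicted P(y = 1) for standardized predictors."""
    X_new = np.asarray(X_new, float)
    if X_new.ndim != 2 or X_new.shape[1] != fit_.beta.shape[0]:
        raise ValueError("X_new has wrong number of columns")
    eta = fit_.intercept + X_new @ fit_.beta
    return 1.0 / (1.0 + np.exp(-eta))


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance (-2 * mean log-likelihood)."""
    p = np.clip(np.asarray(p, float), _P_EPS, 1.0 - _P_EPS)
    y = np.asarray(y, float)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold labels in [0, k)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    spec_template: PenaltySpec,
    k: int = 5,
    criterion: str = "deviance",
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
    lambdas: np.ndarray | None = None,
) -> tuple[float, "np.ndarray"]:
    """Select lambda by stratified k-fold CV on a shared lambda grid.

    The grid is the full-data path truncated at ``df_max`` (so the
    selected model always respects the variable cap); pass ``lambdas`` to
    reuse a precomputed grid. Returns (lambda_star, cv_curve) where
    cv_curve has columns (lambda, mean_loss). Ties in the mean loss break
    toward larger lambda.
    """
    X, y = _check_inputs(X, y)
    if len(y) < 2 * k:
        raise ValueError("need at least 2*k samples")
    if criterion not in ("deviance", "auc"):
        raise ValueError("criterion must be 'deviance' or 'auc'")
    if lambdas is None:
        base = fit_path(
            X, y, spec_template, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, tol=tol,
        )
        lambdas = base.lambdas
    lambdas = np.asarray(lambdas, float)
    fold = _stratified_folds(y, k, seed)
    losses = np.full((k, len(lambdas)), np.nan)
    for f in range(k):
        tr = fold != f
        te = ~tr
        if y[te].size == 0 or y[tr].min() == y[tr].max():
            raise ValueError("a CV fold lost one of the classes")
        # re-standardize the training fold (fold means/sds differ slightly)
        Xtr, ctr, str_ = standardize(X[tr])
        Xte = (X[te] - ctr) / str_
        path = fit_path(
            Xtr, y[tr], spec_template, lambdas=lambdas, tol=tol, enforce_df_max=False
        )
        for i, f_i in enumerate(path.fits):
            p = predict_proba(f_i, Xte)
            if criterion == "deviance":
                losses[f, i] = binomial_deviance(y[te], p)
            else:
                from .metrics import auc as _auc

                losses[f, i] = -_auc(p, y[te])
    mean_loss = losses.mean(axis=0)
    best = int(np.nanargmin(np.round(mean_loss, 12)))
    curve = np.column_stack([lambdas, mean_loss])
    return float(lambdas[best]), curve


def kkt_residual(
    X: np.ndarray, y: np.ndarray, fit_: LogisticFit, spec: PenaltySpec | None = None
) -> float:
    """Max violation of the first-order stationarity conditions.

    For active coordinates the subgradient must vanish; for zero
    coordinates the smooth gradient must lie within [-lam1, lam1].
    """
    spec = spec or fit_.spec
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    p = predict_proba(fit_, X)
    g = X.T @ (p - y) / n + spec.lam2 * fit_.beta
    lam1, a = spec.lam1, spec.a
    res = abs(float(np.mean(p - y)))  # intercept stationarity
    for j, b in enumerate(fit_.beta):
        t = abs(b)
        if t == 0.0:
            res = max(res, max(abs(g[j]) - lam1, 0.0))
        else:
            if t <= lam1:
                dp = lam1
            elif t <= a * lam1:
                dp = (a * lam1 - t) / (a - 1.0)
            else:
                dp = 0.0
            res = max(res, abs(g[j] + math.copysign(dp, b)))
    return res


class ScadRidgeClassifier:
    """sklearn-style wrapper: internal standardization + inner-CV lambda.

    ``alpha=1.0`` with a very large ``a`` gives lasso-like behavior and is
    what the benchmark's Lasso-PLR family uses.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        a: float = 3.7,
        df_max: int = 28,
        inner_k: int = 5,
        n_lambda: int = 50,
        lambda_min_ratio: float = 0.01,
        criterion: str = "deviance",
        seed: int = 0,
        tol: float = 1e-6,
    ) -> None:
        self.alpha = alpha
        self.a = a
        self.df_max = df_max
        self.inner_k = inner_k
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.criterion = criterion
        self.seed = seed
        self.tol = tol
        self.fit_: LogisticFit | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ScadRidgeClassifier":
        Xs, center, scale = standardize(np.asarray(X, float))
        y = np.asarray(y, float)
        template = PenaltySpec(lam=1.0, alpha=self.alpha, a=self.a, df_max=self.df_max)
        path = fit_path(
            Xs, y, template, n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio, tol=self.tol,
        )
        lam_star, curve = cv_select_lambda(
            Xs,
            y,
            template,
            k=self.inner_k,
            criterion=self.criterion,
            seed=self.seed,
            tol=self.tol,
            lambdas=path.lambdas,
        )
        f = path.fits[int(np.argmin(np.abs(path.lambdas - lam_star)))]
        f.center = center
        f.scale = scale
        self.fit_ = f
        self.lambda_ = lam_star
        self.cv_curve_ = curve
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.fit_ is None:
            raise ValueError("classifier is not fitted")
        Xs = (np.asarray(X, float) - self.fit_.center) / self.fit_.scale
        p1 = predict_proba(self.fit_, Xs)
        return np.column_stack([1.0 - p1, p1])
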