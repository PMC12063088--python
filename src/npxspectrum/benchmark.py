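"""Down-sampled, repeated k-fold CV benchmark of classifier families.

Four families are compared on subgroup pairs: the package's own SCAD+ridge
penalized logistic regression, a lasso-like PLR (alpha = 1 with a very
large SCAD shape parameter), random forest, and an RBF-kernel SVM whose
decision values serve as ranking scores. Group-size imbalance is removed
by repeated random down-sampling to the smallest group; standardization,
feature selection, and hyperparameter tuning all happen inside training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import NPXDataset, resolve_group
from .metrics import auc
from .scadridge import ScadRidgeClassifier

__all__ = [
    "FAMILIES",
    "BenchmarkResult",
    "downsample_groups",
    "repeated_cv_auc",
    "compare_all",
]

FAMILIES = ("scad_ridge_plr", "lasso_plr", "random_forest", "svm_radial")


# ---------------------------------------------------------------------------
# family adapters: fit(X, y) + ranking_scores(X)
# ---------------------------------------------------------------------------

class _PLRAdapter:
    def __init__(self, alpha: float, a: float, seed: int, n_lambda: int = 30):
        self.clf = ScadRidgeClassifier(
            alpha=alpha, a=a, df_max=28, n_lambda=n_lambda, seed=seed
        )

    def fit(self, X, y):
        self.clf.fit(X, y)
        return self

    def ranking_scores(self, X):
        return self.clf.predict_proba(X)[:, 1]


class _RFAdapter:
    """Random forest with mtry tuned by a small inner CV."""

    def __init__(self, seed: int, n_estimators: int = 100, inner_k: int = 3):
        self.seed = seed
        self.n_estimators = n_estimators
        self.inner_k = inner_k

    def fit(self, X, y):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        best, best_score = None, -np.inf
        cv = StratifiedKFold(self.inner_k, shuffle=True, random_state=self.seed % 2**31)
        for mf in ("sqrt", 0.5):
            rf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=mf,
                random_state=self.seed % 2**31,
                n_jobs=1,
            )
            sc = cross_val_score(rf, X, y, cv=cv, scoring="roc_auc").mean()
            if sc > best_score:
                best, best_score = mf, sc
        self.model = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=best,
            random_state=self.seed % 2**31,
            n_jobs=1,
        ).fit(X, y)
        return self

    def ranking_scores(self, X):
        return self.model.predict_proba(X)[:, 1]


class _SVMAdapter:
    """RBF SVM on the top-m proteins by training-fold univariate AUC.

    m and the cost C are tuned jointly in a small inner CV; decision
    values (not calibrated probabilities) are the ranking scores.
    """

    def __init__(self, seed: int, inner_k: int = 3):
        self.seed = seed
        self.inner_k = inner_k

    @staticmethod
    def _rank_features(X, y):
        scores = np.array([abs(auc(X[:, j], y) - 0.5) for j in range(X.shape[1])])
        return np.argsort(-scores)

    def fit(self, X, y):
        from sklearn.model_selection import StratifiedKFold
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X = np.asarray(X, float)
        y = np.asarray(y)
        order = self._rank_features(X, y)
        m_grid = sorted({min(10, X.shape[1]), min(25, X.shape[1]), X.shape[1]})
        c_grid = (0.1, 1.0, 10.0)
        cv = StratifiedKFold(self.inner_k, shuffle=True, random_state=self.seed % 2**31)
        best, best_score = None, -np.inf
        for m in m_grid:
            cols = order[:m]
            for C in c_grid:
                fold_scores = []
                for tr, te in cv.split(X, y):
                    sc = StandardScaler().fit(X[tr][:, cols])
                    svm = SVC(kernel="rbf", C=C, gamma="scale").fit(
                        sc.transform(X[tr][:, cols]), y[tr]
                    )
                    dv = svm.decision_function(sc.transform(X[te][:, cols]))
                    fold_scores.append(auc(dv, y[te]))
                mean_sc = float(np.mean(fold_scores))
                if mean_sc > best_score:
                    best, best_score = (m, C), mean_sc
        m, C = best
        self.cols_ = order[:m]
        self.scaler_ = StandardScaler().fit(X[:, self.cols_])
        self.model_ = SVC(kernel="rbf", C=C, gamma="scale").fit(
            self.scaler_.transform(X[:, self.cols_]), y
        )
        return self

    def ranking_scores(self, X):
        X = np.asarray(X, float)[:, self.cols_]
        return self.model_.decision_function(self.scaler_.transform(X))


def make_family(name: str, seed: int):
    if name == "scad_ridge_plr":
        return _PLRAdapter(alpha=0.1, a=3.7, seed=seed)
    if name == "lasso_plr":
        return _PLRAdapter(alpha=1.0, a=1e6, seed=seed)
    if name == "random_forest":
        return _RFAdapter(seed=seed)
    if name == "svm_radial":
        return _SVMAdapter(seed=seed)
    raise ValueError(f"unknown model family {name!r}; expected one of {FAMILIES}")


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    pair: tuple[str, str]
    family: str
    aucs: pd.DataFrame  # columns: repeat, fold, auc
    median_auc: float


def downsample_groups(
    groups: pd.Series, pair: tuple[str, str], seed: int
) -> tuple[list[str], list[str]]:
    """Balanced random subsample: both sides of the pair at the smaller
    side's size. Composite names (e.g. COLONIC_IBD) are pooled before
    down-sampling. Deterministic given seed."""
    rng = np.random.default_rng(seed)
    sides = []
    for name in pair:
        members = resolve_group(name)
        ids = list(groups.index[groups.isin(members)])
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        sides.append(ids)
    n_min = min(len(s) for s in sides)
    out = []
    for ids in sides:
        if len(ids) > n_min:
            ids = list(rng.choice(ids, size=n_min, replace=False))
        out.append(sorted(ids))
    return out[0], out[1]


def repeated_cv_auc(
    ds: NPXDataset,
    groups: pd.Series,
    pair: tuple[str, str],
    family: str,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> BenchmarkResult:
    """Repeated down-sampled stratified k-fold CV, scored by rank AUC.

    Each repeat draws a fresh balanced subsample and fold assignment; the
    family's hyperparameters are re-tuned inside every training fold.
    """
    from sklearn.model_selection import StratifiedKFold

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(repeats)]
    rows = []
    for rep, rs in enumerate(repeat_seeds):
        ids_a, ids_b = downsample_groups(groups, pair, seed=rs)
        if len(ids_a) < k or len(ids_b) < k:
            raise ValueError("down-sampled groups too small for k folds")
        ids = ids_a + ids_b
        y = np.array([1] * len(ids_a) + [0] * len(ids_b))
        X = ds.values.loc[ids].to_numpy(float)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs % 2**31)
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                raise ValueError("fold with a single class")
            model = make_family(family, seed=rs + fold_i).fit(X[tr], y[tr])
            sc = model.ranking_scores(X[te])
            rows.append((rep, fold_i, auc(sc, y[te])))
    aucs = pd.DataFrame(rows, columns=["repeat", "fold", "auc"])
    return BenchmarkResult(
        pair=pair,
        family=family,
        aucs=aucs,
        median_auc=float(aucs["auc"].median()),
    )


def compare_all(
    ds: NPXDataset,
    groups: pd.Series,
    pairs: list[tuple[str, str]],
    families: list[str] | None = None,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Full pair x family grid; returns a tidy table with one row per
    (pair, family, repeat, fold) plus the per-cell median in
    ``median_auc``."""
    families = list(families or FAMILIES)
    frames = []
    for pair in pairs:
        for fam in families:
            res = repeated_cv_auc(ds, groups, pair, fam, k=k, repeats=repeats, seed=seed)
            t = res.aucs.copy()
            t.insert(0, "family", fam)
            t.insert(0, "pair", f"{pair[0]}_vs_{pair[1]}")
            t["median_auc"] = res.median_auc
            frames.append(t)
    return pd.concat(frames, ignore_index=True)
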