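"""Univariate differential screening and PCA overview.

Pairwise Welch t-tests per protein with Benjamini-Hochberg FDR control and
a fold-change rule: a protein is significant for a contrast iff
q < fdr_threshold AND |log2FC| > log2(fc_threshold). Because NPX is
already log2-scale, the log2 fold-change of a contrast A vs B is simply
mean(NPX_A) - mean(NPX_B).

BH is applied within each pairwise contrast across proteins (one
correction per volcano), not pooled across contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NPXDataset, resolve_group

__all__ = [
    "ScreenConfig",
    "AdjustedScreenConfig",
    "welch_t",
    "bh_fdr",
    "pairwise_screen",
    "adjusted_screen",
    "pca_overview",
    "component_group_test",
    "PCAResult",
]


@dataclass(frozen=True)
class ScreenConfig:
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.2

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must be > 1")

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold))


@dataclass(frozen=True)
class AdjustedScreenConfig:
    covariates: tuple[str, ...] = ("Age", "Sex", "DurationYears")
    exclude_prior_surgery: bool = True
    screen: ScreenConfig = field(default_factory=ScreenConfig)


def welch_t(x: np.ndarray, y: np.ndarray, name: str = "") -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Welch-Satterthwaite df, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"welch_t needs >= 2 values per group ({name or 'unnamed'})")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx <= 0 and vy <= 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError(f"degenerate zero variance in both groups ({name or 'unnamed'})")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped to
    [0, 1]. NaN entries propagate as NaN and do not count toward m.
    """
    p = np.asarray(pvals, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    out[ok] = q
    return out


def _group_matrix(ds: NPXDataset, groups: pd.Series, name: str) -> pd.DataFrame:
    members = resolve_group(name)
    ids = groups.index[groups.isin(members)]
    ids = [s for s in ds.sample_ids if s in set(ids)]
    if not ids:
        raise ValueError(f"group {name!r} has no samples in the dataset")
    return ds.values.loc[ids]


def pairwise_screen(
    ds: NPXDataset,
    groups: pd.Series,
    pairs: list[tuple[str, str]],
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Welch + BH + fold-change screen, one row per (protein, contrast)."""
    cfg = cfg or ScreenConfig()
    frames = []
    for ga, gb in pairs:
        A = _group_matrix(ds, groups, ga)
        B = _group_matrix(ds, groups, gb)
        if len(A) < 2 or len(B) < 2:
            raise ValueError(f"pair ({ga}, {gb}) has a group with < 2 samples")
        rows = []
        for prot in ds.protein_names:
            t, df, p = welch_t(A[prot].to_numpy(), B[prot].to_numpy(), name=prot)
            log2fc = float(np.nanmean(A[prot])) - float(np.nanmean(B[prot]))
            rows.append((prot, f"{ga}_vs_{gb}", log2fc, t, df, p))
        tab = pd.DataFrame(
            rows, columns=["protein", "contrast", "log2fc", "t", "df", "p"]
        )
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        tab["significant"] = (tab["q"] < cfg.fdr_threshold) & (
            tab["log2fc"].abs() > cfg.log2fc_threshold
        )
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def adjusted_screen(
    ds: NPXDataset,
    meta: pd.DataFrame,
    groups: pd.Series,
    pairs: list[tuple[str, str]],
    cfg: AdjustedScreenConfig | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted screen via per-protein linear models.

    For each pair, fits NPX ~ group + covariates by OLS on the two groups'
    samples; the group coefficient is the adjusted log2FC. Samples with
    prior IBD-related surgery are excluded when configured.
    """
    import statsmodels.api as sm

    cfg = cfg or AdjustedScreenConfig()
    frames = []
    for ga, gb in pairs:
        A = _group_matrix(ds, groups, ga)
        B = _group_matrix(ds, groups, gb)
        ids = list(A.index) + list(B.index)
        sub = meta.loc[ids]
        if cfg.exclude_prior_surgery:
            keep = ~sub["PriorSurgery"].astype(bool)
            ids = [s for s, k in zip(ids, keep) if k]
            sub = meta.loc[ids]
        y_group = np.array([1.0 if s in set(A.index) else 0.0 for s in ids])
        design = {"group": y_group}
        for cov in cfg.covariates:
            col = sub[cov]
            if cov == "Sex":
                design["Sex"] = (col.astype(str) == "M").astype(float).to_numpy()
            else:
                design[cov] = col.astype(float).to_numpy()
        Xd = pd.DataFrame(design, index=ids)
        if np.isnan(Xd.to_numpy()).any():
            raise ValueError("missing covariate values among included samples")
        for cov in Xd.columns:
            if Xd[cov].nunique() < 2:
                raise ValueError(f"covariate {cov!r} is constant (rank-deficient design)")
        Xmat = sm.add_constant(Xd, has_constant="add")
        if np.linalg.matrix_rank(Xmat.to_numpy()) < Xmat.shape[1]:
            raise ValueError("rank-deficient design matrix")
        rows = []
        for prot in ds.protein_names:
            yv = ds.values.loc[ids, prot].to_numpy(float)
            mask = ~np.isnan(yv)
            res = sm.OLS(yv[mask], Xmat.to_numpy()[mask]).fit()
            coef = float(res.params[1])  # group column
            pval = float(res.pvalues[1])
            rows.append((prot, f"{ga}_vs_{gb}", coef, pval, int(mask.sum())))
        tab = pd.DataFrame(
            rows, columns=["protein", "contrast", "adj_log2fc", "p", "n"]
        )
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        sc = cfg.screen
        tab["significant"] = (tab["q"] < sc.fdr_threshold) & (
            tab["adj_log2fc"].abs() > sc.log2fc_threshold
        )
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray


def pca_overview(ds: NPXDataset, n_components: int = 10, scale: bool = False) -> PCAResult:
    """Column-centered PCA of the NPX matrix with a deterministic sign fix.

    Missing values are mean-imputed (with a warning via logging). Each
    component is oriented so its largest-|loading| element is positive.
    """
    import logging

    if ds.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    if ds.n_proteins < 2:
        raise ValueError("PCA needs at least 2 proteins")
    X = ds.values.to_numpy(float)
    if np.isnan(X).any():
        logging.getLogger(__name__).warning("mean-imputing missing NPX values for PCA")
        col_mean = np.nanmean(X, axis=0)
        nan_r, nan_c = np.where(np.isnan(X))
        X = X.copy()
        X[nan_r, nan_c] = col_mean[nan_c]
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    n_components = min(n_components, min(Xc.shape) - 1 if min(Xc.shape) > 1 else 1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| element of each component positive
    for c in range(n_components):
        jmax = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, jmax] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    total_var = (Xc**2).sum()
    evr = S**2 / total_var
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ds.values.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=ds.values.columns, columns=comp_names),
        explained_variance_ratio=evr,
    )


def component_group_test(
    scores: pd.Series, groups: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across groups on one component plus Dunn's post hoc.

    Dunn z-statistics use the tie-corrected pooled rank variance; pairwise
    p-values are BH-adjusted. Returns (KW statistic, KW p, Dunn table).
    """
    common = scores.index.intersection(groups.index)
    s = scores.loc[common].to_numpy(float)
    g = groups.loc[common].to_numpy()
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [s[g == lab] for lab in labels]
    if any(len(x) < 2 for x in samples):
        raise ValueError("each group needs >= 2 samples")
    kw_stat, kw_p = stats.kruskal(*samples)

    n = len(s)
    ranks = stats.rankdata(s)
    mean_rank = {lab: ranks[g == lab].mean() for lab in labels}
    n_of = {lab: int((g == lab).sum()) for lab in labels}
    # tie correction for the rank variance
    _, counts = np.unique(s, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(var_base * (1.0 / n_of[a] + 1.0 / n_of[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((str(a), str(b), float(z), float(p)))
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    dunn["q"] = bh_fdr(dunn["p"].to_numpy())
    return float(kw_stat), float(kw_p), dunn
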