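"""Disease-spectrum probability scores from nested cross-validation.

A CD-vs-UC penalized logistic model (SCAD + ridge) is trained on CD and UC
samples only. Every held-out CD/UC sample receives the average predicted
CD probability over ``repeats`` models that differ only in the random
inner-CV lambda selection; non-training groups (IBD-U, HC) are projected
through repeated full-data models. Group-level summaries place subgroups
along the resulting 0 (UC-like) to 1 (CD-like) continuum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NPXDataset, resolve_group
from .metrics import auc
from .scadridge import ScadRidgeClassifier

__all__ = [
    "SpectrumSummary",
    "nested_cv_scores",
    "group_medians",
    "anova_tukey",
    "coefficient_stability",
    "cohort_holdout_scores",
    "score_auc",
]

CD_GROUPS = ("CD_L1", "CD_L2", "CD_L3")


@dataclass
class SpectrumSummary:
    medians: pd.DataFrame  # per group: n, median, q1, q3
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pair, meandiff, lower, upper, p_adj, reject


def _training_labels(groups: pd.Series) -> pd.Series:
    """Binary labels on CD/UC samples: CD = 1, UC = 0."""
    is_cd = groups.isin(CD_GROUPS)
    is_uc = groups == "UC"
    y = pd.Series(np.where(is_cd, 1.0, 0.0), index=groups.index)
    return y[is_cd | is_uc]


def _repeat_seeds(seed: int, repeats: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(repeats)]


def _make_clf(spec_template: dict | None, seed: int) -> ScadRidgeClassifier:
    kw = dict(spec_template or {})
    kw["seed"] = seed
    return ScadRidgeClassifier(**kw)


def _outer_folds(y: np.ndarray, outer, seed: int) -> np.ndarray:
    """Fold labels: LOO gives each sample its own fold; otherwise
    stratified k-fold with deterministic shuffling."""
    n = len(y)
    if outer == "loo":
        return np.arange(n)
    k = int(outer)
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def nested_cv_scores(
    ds: NPXDataset,
    groups: pd.Series,
    outer: str | int = "loo",
    inner_k: int = 5,
    repeats: int = 10,
    spec_template: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-sample CD-vs-UC probability scores for every sample.

    ``spec_template`` holds keyword arguments of
    :class:`~npxspectrum.scadridge.ScadRidgeClassifier` (alpha, a, df_max,
    n_lambda, ...). The outer fold structure is fixed by ``seed``; the
    ``repeats`` models per fold differ only in their inner-CV seeds.

    Returns a frame with columns sample_id, group, score, in_training,
    n_repeats.
    """
    y_all = _training_labels(groups)
    train_ids = [s for s in ds.sample_ids if s in set(y_all.index)]
    if not train_ids:
        raise ValueError("no CD/UC samples to train on")
    y = y_all.loc[train_ids].to_numpy()
    X = ds.values.loc[train_ids].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("training data must contain both CD and UC")
    spec_template = dict(spec_template or {})
    spec_template.setdefault("inner_k", inner_k)
    rseeds = _repeat_seeds(seed, repeats)

    fold = _outer_folds(y, outer, seed)
    scores = np.zeros(len(train_ids))
    for f in np.unique(fold):
        te = fold == f
        tr = ~te
        if y[tr].min() == y[tr].max():
            raise ValueError(f"outer fold {f} leaves a single-class training set")
        preds = np.zeros((repeats, int(te.sum())))
        for r, rs in enumerate(rseeds):
            clf = _make_clf(spec_template, rs).fit(X[tr], y[tr])
            preds[r] = clf.predict_proba(X[te])[:, 1]
        scores[te] = preds.mean(axis=0)

    rows = [
        {
            "sample_id": sid,
            "group": groups.loc[sid],
            "score": float(sc),
            "in_training": True,
            "n_repeats": repeats,
        }
        for sid, sc in zip(train_ids, scores)
    ]

    # projection: score non-CD/UC samples with repeated full-data models
    other_ids = [
        s for s in ds.sample_ids if s in set(groups.index) and s not in set(train_ids)
    ]
    if other_ids:
        Xo = ds.values.loc[other_ids].to_numpy(float)
        preds = np.zeros((repeats, len(other_ids)))
        for r, rs in enumerate(rseeds):
            clf = _make_clf(spec_template, rs).fit(X, y)
            preds[r] = clf.predict_proba(Xo)[:, 1]
        for sid, sc in zip(other_ids, preds.mean(axis=0)):
            rows.append(
                {
                    "sample_id": sid,
                    "group": groups.loc[sid],
                    "score": float(sc),
                    "in_training": False,
                    "n_repeats": repeats,
                }
            )
    return pd.DataFrame(rows)


def group_medians(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-group score median and IQR."""
    if scores.empty:
        raise ValueError("no scores")
    out = (
        scores.groupby("group")["score"]
        .agg(
            n="size",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return out


def anova_tukey(
    scores: pd.DataFrame,
    include_groups: list[str] | None = None,
    alpha: float = 0.05,
) -> SpectrumSummary:
    """One-way ANOVA on group means plus Tukey HSD (Tukey-Kramer for
    unequal n) with simultaneous CIs.

    HC is excluded by default (scored by projection only); pass
    ``include_groups`` to control the group set explicitly.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = scores.copy()
    if include_groups is None:
        df = df[df["group"] != "HC"]
    else:
        df = df[df["group"].isin(include_groups)]
    counts = df.groupby("group").size()
    counts = counts[counts >= 2]
    df = df[df["group"].isin(counts.index)]
    if counts.size < 2:
        raise ValueError("need >= 2 groups with >= 2 scores each")
    samples = [df.loc[df["group"] == g, "score"].to_numpy() for g in counts.index]
    if all(np.all(s == s[0]) for s in samples):
        raise ValueError("zero within-group variance everywhere")
    f_stat, f_p = stats.f_oneway(*samples)

    res = pairwise_tukeyhsd(
        df["score"].to_numpy(), df["group"].to_numpy(), alpha=alpha
    )
    from itertools import combinations

    pairs = list(combinations(range(len(res.groupsunique)), 2))
    tukey = pd.DataFrame(
        {
            "group_a": [str(res.groupsunique[i]) for i, _ in pairs],
            "group_b": [str(res.groupsunique[j]) for _, j in pairs],
            "meandiff": res.meandiffs,
            "lower": res.confint[:, 0],
            "upper": res.confint[:, 1],
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    return SpectrumSummary(
        medians=group_medians(df),
        anova_f=float(f_stat),
        anova_p=float(f_p),
        tukey=tukey,
    )


def coefficient_stability(
    ds: NPXDataset,
    groups: pd.Series,
    n_refits: int = 1000,
    spec_template: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient distributions over repeated full-data fits.

    Each refit reruns the inner-CV lambda selection with a fresh seed, so
    the spread reflects the randomness of the tuning step. Coefficients
    are on the standardized-predictor scale; proteins are returned ranked
    by median |coefficient|.
    """
    y_all = _training_labels(groups)
    train_ids = [s for s in ds.sample_ids if s in set(y_all.index)]
    y = y_all.loc[train_ids].to_numpy()
    X = ds.values.loc[train_ids].to_numpy(float)
    coefs = np.zeros((n_refits, ds.n_proteins))
    for r, rs in enumerate(_repeat_seeds(seed, n_refits)):
        clf = _make_clf(spec_template, rs).fit(X, y)
        coefs[r] = clf.fit_.beta
    out = pd.DataFrame(
        {
            "protein": ds.protein_names,
            "median_coef": np.median(coefs, axis=0),
            "q1": np.quantile(coefs, 0.25, axis=0),
            "q3": np.quantile(coefs, 0.75, axis=0),
            "selection_freq": (coefs != 0.0).mean(axis=0),
            "n_refits": n_refits,
        }
    )
    return out.reindex(
        out["median_coef"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def cohort_holdout_scores(
    ds: NPXDataset,
    meta: pd.DataFrame,
    groups: pd.Series,
    holdout_cohort: str,
    treatment_naive_only: bool = True,
    repeats: int = 10,
    spec_template: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Scores for a held-out cohort from models trained on the rest.

    Training uses CD/UC samples outside ``holdout_cohort``; scored samples
    are the holdout cohort's members (optionally restricted to
    treatment-naive patients).
    """
    if holdout_cohort not in set(meta["Cohort"]):
        raise ValueError(f"cohort {holdout_cohort!r} not present")
    in_holdout = meta["Cohort"] == holdout_cohort
    y_all = _training_labels(groups)
    train_ids = [
        s for s in ds.sample_ids if s in set(y_all.index) and not in_holdout.get(s, False)
    ]
    if not train_ids:
        raise ValueError("empty training set after removing the holdout cohort")
    y = y_all.loc[train_ids].to_numpy()
    if y.min() == y.max():
        raise ValueError("training set lost one of the classes")

    score_ids = [s for s in ds.sample_ids if in_holdout.get(s, False)]
    if treatment_naive_only:
        naive = meta["TreatmentNaive"].astype(bool)
        score_ids = [s for s in score_ids if naive.get(s, False)]
    if not score_ids:
        raise ValueError("no holdout samples left after filtering")

    X = ds.values.loc[train_ids].to_numpy(float)
    Xo = ds.values.loc[score_ids].to_numpy(float)
    preds = np.zeros((repeats, len(score_ids)))
    for r, rs in enumerate(_repeat_seeds(seed, repeats)):
        clf = _make_clf(spec_template, rs).fit(X, y)
        preds[r] = clf.predict_proba(Xo)[:, 1]
    return pd.DataFrame(
        {
            "sample_id": score_ids,
            "group": [groups.get(s) for s in score_ids],
            "score": preds.mean(axis=0),
            "in_training": False,
            "n_repeats": repeats,
        }
    )


def score_auc(
    scores: pd.DataFrame,
    positive: str | list[str],
    negative: str | list[str],
) -> float:
    """AUC of the probability scores for one (possibly composite) contrast.

    ``positive``/``negative`` are group names; composites like
    COLONIC_IBD resolve to their member groups.
    """
    def _expand(g) -> tuple[str, ...]:
        names: tuple[str, ...] = ()
        for item in [g] if isinstance(g, str) else list(g):
            names += resolve_group(item)
        return names

    pos, neg = _expand(positive), _expand(negative)
    sub = scores[scores["group"].isin(pos + neg)]
    labels = sub["group"].isin(pos).astype(int).to_numpy()
    if labels.min() == labels.max():
        raise ValueError("subset contains a single class")
    return auc(sub["score"].to_numpy(), labels)
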