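"""Synthetic NPX cohort generator.

Samples a cohort whose structure matches what the analysis assumes: a
latent ileal<->colonic position theta in [0, 1] per disease group loading a
sparse protein signature, an IBD-vs-healthy offset on a protein subset,
per-batch location shifts, left-censoring at a per-protein LOD, and
age/sex/duration covariate effects. Ground truth is returned alongside the
data so recovery can be tested without external data.

Generative model for sample i, protein j::

    NPX_ij = mu_j + w_j * theta_g(i) + ibd_i * delta_j
             + batch_shift_b(i),j + c_age*age_i + c_sex*sex_i + c_dur*dur_i
             + eps_ij,     eps_ij ~ N(0, residual_sd^2)

Healthy controls have theta = 0 and no IBD offset. Below-LOD values are
kept numerically and flagged, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import NPXDataset

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "plant_lod_violations"]

#: analysis-group label -> (Diagnosis, Location) used in emitted metadata
_GROUP_TO_DX: dict[str, tuple[str, str | None]] = {
    "HC": ("HC", None),
    "UC": ("UC", None),
    "IBDU": ("IBD-U", None),
    "CD_L1": ("CD", "L1"),
    "CD_L2": ("CD", "L2"),
    "CD_L3": ("CD", "L3"),
}

DEFAULT_GROUP_POSITIONS = {"UC": 0.0, "CD_L2": 0.35, "CD_L3": 0.8, "CD_L1": 1.0}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``group_positions`` holds the latent continuum position theta of each
    IBD group; HC is handled separately (theta = 0, no IBD offset) and
    needs no entry.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 60, "UC": 60, "CD_L2": 40, "CD_L3": 50, "CD_L1": 50}
    )
    group_positions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_POSITIONS)
    )
    n_proteins: int = 86
    n_signal: int = 10
    effect_scale: float = 0.8
    ibd_shift: float = 0.0
    n_ibd_shift_proteins: int = 10
    n_batches: int = 1
    batch_sd: float = 0.0
    residual_sd: float = 1.0
    lod_quantile: float = 0.0
    qc_fail_rate: float = 0.0
    covariate_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per-year age, sex, per-year duration
    n_cohorts: int = 1
    surgery_rate: float = 0.0
    treatment_naive_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes is empty")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be > 0")
            if g not in _GROUP_TO_DX:
                raise ValueError(f"unknown group {g!r}")
            if g not in ("HC",) and g not in self.group_positions:
                raise ValueError(f"group_positions missing entry for group {g!r}")
        for g, theta in self.group_positions.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"theta for {g!r} outside [0, 1]")
        if not (self.n_proteins > 0 and 0 <= self.n_signal <= self.n_proteins):
            raise ValueError("need 0 <= n_signal <= n_proteins and n_proteins > 0")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must lie in [0, 1)")
        if not 0.0 <= self.qc_fail_rate < 1.0:
            raise ValueError("qc_fail_rate must lie in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.n_batches < 1 or self.n_cohorts < 1:
            raise ValueError("n_batches and n_cohorts must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    signal_proteins: list[str]
    effects: pd.Series  # per-protein w_j; zero off the signature
    ibd_proteins: list[str]
    ibd_effects: pd.Series  # per-protein delta_j
    group_positions: dict[str, float]
    baseline: pd.Series  # mu_j
    batch_shifts: pd.DataFrame  # batch x protein
    censored_fraction: pd.Series
    qc_failures: list[str]

    def to_dict(self) -> dict:
        return {
            "signal_proteins": self.signal_proteins,
            "effects": self.effects.to_dict(),
            "ibd_proteins": self.ibd_proteins,
            "ibd_effects": self.ibd_effects.to_dict(),
            "group_positions": self.group_positions,
            "baseline": self.baseline.to_dict(),
            "batch_shifts": {b: row.to_dict() for b, row in self.batch_shifts.iterrows()},
            "censored_fraction": self.censored_fraction.to_dict(),
            "qc_failures": self.qc_failures,
        }


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[NPXDataset, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort; identical config and seed give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins = [f"P{j + 1:03d}" for j in range(config.n_proteins)]
    mu = pd.Series(rng.normal(3.0, 1.0, config.n_proteins), index=proteins, name="mu")

    # sparse continuum signature: alternating signs so the score has both ends
    signal = list(rng.choice(proteins, size=config.n_signal, replace=False))
    w = pd.Series(0.0, index=proteins, name="w")
    signs = np.where(np.arange(config.n_signal) % 2 == 0, 1.0, -1.0)
    w.loc[signal] = signs * config.effect_scale

    # IBD-vs-HC offset on a subset disjoint from nothing in particular
    n_delta = min(config.n_ibd_shift_proteins, config.n_proteins)
    ibd_proteins = list(rng.choice(proteins, size=n_delta, replace=False)) if config.ibd_shift else []
    delta = pd.Series(0.0, index=proteins, name="delta")
    if ibd_proteins:
        delta.loc[ibd_proteins] = config.ibd_shift

    batches = [f"B{b + 1}" for b in range(config.n_batches)]
    batch_shifts = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, (config.n_batches, config.n_proteins))
        if config.batch_sd > 0
        else np.zeros((config.n_batches, config.n_proteins)),
        index=batches,
        columns=proteins,
    )

    rows, meta_rows, sample_ids, batch_of = [], [], [], []
    c_age, c_sex, c_dur = config.covariate_effects
    i = 0
    for g in sorted(config.group_sizes):
        n_g = config.group_sizes[g]
        theta = 0.0 if g == "HC" else float(config.group_positions[g])
        is_ibd = g != "HC"
        dx, loc = _GROUP_TO_DX[g]
        for _ in range(n_g):
            sid = f"S{i + 1:05d}"
            age = rng.uniform(18.0, 80.0)
            sex = int(rng.random() < 0.5)
            duration = 0.0 if not is_ibd else min(rng.exponential(8.0), 40.0)
            batch = batches[int(rng.integers(config.n_batches))]
            cohort = f"C{int(rng.integers(config.n_cohorts)) + 1}"
            surgery = bool(is_ibd and rng.random() < config.surgery_rate)
            naive = bool(is_ibd and rng.random() < config.treatment_naive_rate)
            signal_part = (
                mu.to_numpy()
                + w.to_numpy() * theta
                + (delta.to_numpy() if is_ibd else 0.0)
                + batch_shifts.loc[batch].to_numpy()
                + c_age * age
                + c_sex * sex
                + c_dur * duration
            )
            eps = rng.normal(0.0, config.residual_sd, config.n_proteins)
            rows.append(signal_part + eps)
            sample_ids.append(sid)
            batch_of.append(batch)
            meta_rows.append(
                {
                    "Diagnosis": dx,
                    "Location": loc,
                    "Behavior": "B1" if dx == "CD" else None,
                    "Extent": "E2" if dx == "UC" else None,
                    "Age": age,
                    "Sex": "M" if sex else "F",
                    "DurationYears": duration,
                    "PriorSurgery": surgery,
                    "TreatmentNaive": naive,
                    "Cohort": cohort,
                }
            )
            i += 1

    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=proteins)
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="SampleID"))
    batch_series = pd.Series(batch_of, index=values.index, name="batch")

    # LOD at the requested quantile of each protein's realized distribution;
    # lod_quantile = 0 puts the LOD below every observed value (no censoring).
    if config.lod_quantile > 0:
        lod = values.quantile(config.lod_quantile, axis=0)
    else:
        lod = values.min(axis=0) - 1.0
    lod.name = "lod"
    below = values.lt(lod, axis=1)

    qc_fail = rng.random(len(sample_ids)) < config.qc_fail_rate
    qc_pass = pd.Series(~qc_fail, index=values.index, name="qc_pass")

    ds = NPXDataset(
        values=values,
        lod=lod.astype(float),
        batch=batch_series,
        qc_pass=qc_pass,
        below_lod=below,
    )
    truth = SyntheticTruth(
        signal_proteins=signal,
        effects=w,
        ibd_proteins=ibd_proteins,
        ibd_effects=delta,
        group_positions={g: (0.0 if g == "HC" else float(config.group_positions[g]))
                         for g in config.group_sizes},
        baseline=mu,
        batch_shifts=batch_shifts,
        censored_fraction=below.mean(axis=0),
        qc_failures=[s for s, f in zip(sample_ids, qc_fail) if f],
    )
    return ds, meta, truth


def plant_lod_violations(
    ds: NPXDataset, proteins: Sequence[str], fraction: float
) -> NPXDataset:
    """Raise the LOD of the named proteins so that at least
    ``ceil(fraction * n_samples)`` of their values fall below it.

    Other proteins are untouched. Used as a fixture for the >90%-below-LOD
    exclusion rule.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    unknown = [p for p in proteins if p not in set(ds.protein_names)]
    if unknown:
        raise KeyError(f"unknown proteins: {unknown}")
    if isinstance(ds.lod, pd.DataFrame):
        raise ValueError("plant_lod_violations requires a per-protein LOD series")

    out = ds.copy()
    n = ds.n_samples
    k = int(np.ceil(fraction * n))
    for p in proteins:
        vals = np.sort(out.values[p].to_numpy(float))
        if k >= n:
            new_lod = vals[-1] + 1.0
        else:
            new_lod = 0.5 * (vals[k - 1] + vals[k])
        out.lod.loc[p] = new_lod
        out.below_lod[p] = out.values[p] < new_lod
    return out
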