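"""Preprocessing: QC exclusion, assay exclusion, below-LOD filtering, batch
adjustment, and mapping of sample metadata to analysis groups.

Conventions (tested boundaries):

* a value is "below LOD" iff it is *strictly* less than the LOD;
* a protein is dropped iff its below-LOD fraction is *strictly* greater
  than the threshold (default 0.90), computed over non-missing values;
* missing values never enter denominators and are never imputed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AnalysisGroup, NPXDataset

__all__ = [
    "PreprocessReport",
    "apply_qc",
    "exclude_assays",
    "exclude_below_lod",
    "adjust_batches",
    "assign_groups",
]

logger = logging.getLogger(__name__)

BATCH_METHODS = ("median_center", "reference_align", "location_scale")


@dataclass
class PreprocessReport:
    """Audit trail of removals, one entry per preprocessing step."""

    removed_samples: dict[str, list[str]] = field(default_factory=dict)
    removed_proteins: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "removed_proteins": self.removed_proteins,
            "warnings": self.warnings,
        }


def apply_qc(ds: NPXDataset, report: PreprocessReport | None = None) -> NPXDataset:
    """Drop samples whose QC flag failed."""
    keep = ds.qc_pass[ds.qc_pass].index
    removed = [s for s in ds.sample_ids if s not in set(keep)]
    if report is not None:
        report.removed_samples["qc"] = removed
    if len(keep) == 0:
        logger.warning("apply_qc removed every sample")
    return ds.select_samples(keep)


def exclude_assays(
    ds: NPXDataset, names: list[str], report: PreprocessReport | None = None
) -> NPXDataset:
    """Remove named assays; unknown names are reported, not fatal."""
    present = [n for n in names if n in set(ds.protein_names)]
    unknown = [n for n in names if n not in set(ds.protein_names)]
    if unknown:
        logger.warning("exclude_assays: unknown assay names %s", unknown)
        if report is not None:
            report.warnings.append(f"unknown assays ignored: {unknown}")
    if report is not None:
        report.removed_proteins["assay_exclusion"] = present
    keep = [p for p in ds.protein_names if p not in set(present)]
    return ds.select_proteins(keep)


def exclude_below_lod(
    ds: NPXDataset,
    max_fraction: float = 0.90,
    report: PreprocessReport | None = None,
) -> NPXDataset:
    """Drop proteins whose below-LOD fraction exceeds ``max_fraction``.

    Strict ">": a protein with exactly 90.0% of non-missing values below
    its LOD is retained at the default threshold.
    """
    non_missing = ds.values.notna().sum(axis=0)
    below = (ds.below_lod & ds.values.notna()).sum(axis=0)
    frac = below / non_missing.replace(0, np.nan)
    drop = frac.index[frac > max_fraction].tolist()
    if report is not None:
        report.removed_proteins["below_lod"] = drop
    keep = [p for p in ds.protein_names if p not in set(drop)]
    return ds.select_proteins(keep)


def adjust_batches(
    ds: NPXDataset,
    method: str = "median_center",
    reference_batch: str | None = None,
    min_batch_size: int = 3,
    report: PreprocessReport | None = None,
) -> NPXDataset:
    """Location(-scale) batch adjustment, per protein.

    methods
    -------
    median_center
        Subtract the batch median, add the global median.
    reference_align
        Shift every batch's per-protein median onto the reference batch's.
    location_scale
        reference_align plus matching of the robust scale (MAD).

    Batches smaller than ``min_batch_size`` are passed through unchanged
    (with a warning). LODs are transformed identically, which turns the
    per-protein LOD into a per-batch LOD table.
    """
    if method not in BATCH_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {BATCH_METHODS}")
    batches = pd.unique(ds.batch.dropna())
    if len(batches) == 0:
        raise ValueError("no batch labels present")
    if method in ("reference_align", "location_scale"):
        if reference_batch is None:
            reference_batch = batches[0]
        if reference_batch not in set(batches):
            raise ValueError(f"reference batch {reference_batch!r} absent")

    values = ds.values.copy()
    lod_in = ds.lod_for_samples()
    lod_out = lod_in.copy()

    global_median = values.median(axis=0)
    if method in ("reference_align", "location_scale"):
        ref_rows = ds.batch == reference_batch
        target_loc = values.loc[ref_rows].median(axis=0)
        target_scale = (values.loc[ref_rows] - target_loc).abs().median(axis=0)
    else:
        target_loc = global_median
        target_scale = None

    small: list[str] = []
    for b in batches:
        rows = (ds.batch == b).reindex(values.index, fill_value=False)
        n_b = int(rows.sum())
        if n_b < min_batch_size:
            small.append(str(b))
            continue
        loc_b = values.loc[rows].median(axis=0)
        if method == "location_scale":
            scale_b = (values.loc[rows] - loc_b).abs().median(axis=0)
            ratio = (target_scale / scale_b.replace(0, np.nan)).fillna(1.0)
            values.loc[rows] = (values.loc[rows] - loc_b) * ratio + target_loc
            lod_out.loc[rows] = (lod_in.loc[rows] - loc_b) * ratio + target_loc
        else:
            shift = target_loc - loc_b
            values.loc[rows] = values.loc[rows] + shift
            lod_out.loc[rows] = lod_in.loc[rows] + shift
    if small:
        msg = f"batches below {min_batch_size} samples passed through unchanged: {small}"
        logger.warning(msg)
        if report is not None:
            report.warnings.append(msg)

    # collapse the per-sample LOD matrix to one row per batch
    lod_by_batch = lod_out.groupby(ds.batch).first()
    return NPXDataset(
        values=values,
        lod=lod_by_batch,
        batch=ds.batch.copy(),
        qc_pass=ds.qc_pass.copy(),
        below_lod=ds.below_lod.copy(),
    )


def assign_groups(meta: pd.DataFrame, strict: bool = True) -> pd.Series:
    """Map each sample to its primary :class:`AnalysisGroup`.

    UC maps to UC regardless of extent; CD maps by Montreal location
    (L1/L2/L3). CD with only an L4 (upper-GI) modifier is excluded from
    location groups with a warning; CD with missing location is an error
    when ``strict``.
    """
    groups: dict[str, str] = {}
    missing_loc: list[str] = []
    l4_only: list[str] = []
    for sid, row in meta.iterrows():
        dx = row["Diagnosis"]
        if dx == "HC":
            groups[sid] = AnalysisGroup.HC.value
        elif dx == "UC":
            groups[sid] = AnalysisGroup.UC.value
        elif dx == "IBD-U":
            groups[sid] = AnalysisGroup.IBDU.value
        elif dx == "CD":
            loc = row["Location"]
            loc = None if pd.isna(loc) else str(loc)
            base = None
            if loc is not None:
                for primary in ("L1", "L2", "L3"):
                    if loc.startswith(primary):
                        base = primary
                        break
            if base is not None:
                groups[sid] = f"CD_{base}"
            elif loc is not None and loc.startswith("L4"):
                l4_only.append(sid)
            else:
                missing_loc.append(sid)
    if l4_only:
        logger.warning("CD samples with isolated L4 excluded from location groups: %s", l4_only)
    if missing_loc and strict:
        raise ValueError(f"CD samples missing Montreal location: {missing_loc}")
    return pd.Series(groups, name="group")
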