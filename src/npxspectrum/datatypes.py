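"""Core data containers for NPX proteomics matrices and sample metadata.

NPX values are log2-scale relative protein abundances (arbitrary units).
Each protein carries a limit of detection (LOD) on the same scale; values
below the LOD are flagged but retained numerically so that preprocessing
stays reversible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "NPXDataset",
    "AnalysisGroup",
    "COMPOSITE_GROUPS",
    "METADATA_COLUMNS",
    "validate_metadata",
]

#: Required columns of a sample-metadata table (indexed by SampleID).
METADATA_COLUMNS = [
    "Diagnosis",
    "Location",
    "Behavior",
    "Extent",
    "Age",
    "Sex",
    "DurationYears",
    "PriorSurgery",
    "TreatmentNaive",
    "Cohort",
]


class AnalysisGroup(str, Enum):
    """Primary analysis groups: healthy controls, UC, and CD by Montreal location."""

    HC = "HC"
    UC = "UC"
    IBDU = "IBDU"
    CD_L1 = "CD_L1"  # ileal CD
    CD_L2 = "CD_L2"  # colonic CD
    CD_L3 = "CD_L3"  # ileocolonic CD

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Composite groups resolvable to unions of primary groups.
COMPOSITE_GROUPS: dict[str, tuple[str, ...]] = {
    # exclusively colonic inflammation: UC plus colonic CD
    "COLONIC_IBD": (AnalysisGroup.UC.value, AnalysisGroup.CD_L2.value),
    # all CD regardless of location
    "CD": (
        AnalysisGroup.CD_L1.value,
        AnalysisGroup.CD_L2.value,
        AnalysisGroup.CD_L3.value,
    ),
}


def resolve_group(name: str) -> tuple[str, ...]:
    """Resolve a (possibly composite) group name to primary group labels."""
    key = str(name)
    if key in COMPOSITE_GROUPS:
        return COMPOSITE_GROUPS[key]
    return (AnalysisGroup(key).value,)


@dataclass
class NPXDataset:
    """Samples x proteins matrix of log2 NPX values with per-protein LOD.

    Attributes
    ----------
    values : pd.DataFrame
        Numeric matrix, index = sample ids, columns = protein names.
    lod : pd.Series or pd.DataFrame
        Per-protein LOD (Series indexed by protein), or per-batch LODs
        (DataFrame, index = batch labels, columns = proteins) after batch
        adjustment.
    batch : pd.Series
        Per-sample batch/plate label.
    qc_pass : pd.Series
        Per-sample boolean QC flag (True = keep).
    below_lod : pd.DataFrame
        Boolean mask, same shape as ``values``; True where the measured
        value fell strictly below the protein's LOD.
    """

    values: pd.DataFrame
    lod: pd.Series | pd.DataFrame
    batch: pd.Series
    qc_pass: pd.Series
    below_lod: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate protein names")
        self.batch = self.batch.reindex(self.values.index)
        self.qc_pass = self.qc_pass.reindex(self.values.index).astype(bool)
        if self.below_lod is None:
            self.below_lod = self.values.lt(self.lod_for_samples())
        self.below_lod = self.below_lod.reindex(
            index=self.values.index, columns=self.values.columns
        ).fillna(False).astype(bool)
        self._check_alignment()

    def _check_alignment(self) -> None:
        if isinstance(self.lod, pd.DataFrame):
            missing = set(self.values.columns) - set(self.lod.columns)
        else:
            missing = set(self.values.columns) - set(self.lod.index)
        if missing:
            raise ValueError(f"LOD missing for proteins: {sorted(missing)[:5]}")

    # -- basic properties -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def lod_for_samples(self) -> pd.DataFrame:
        """Per-sample, per-protein LOD matrix (broadcasting per-batch LODs)."""
        if isinstance(self.lod, pd.DataFrame):
            return self.lod.reindex(self.batch.values).set_axis(self.values.index)[
                self.values.columns
            ]
        return pd.DataFrame(
            np.broadcast_to(
                self.lod.reindex(self.values.columns).to_numpy(float),
                self.values.shape,
            ),
            index=self.values.index,
            columns=self.values.columns,
        )

    # -- subsetting --------------------------------------------------------
    def select_samples(self, ids: Iterable[str]) -> "NPXDataset":
        ids = [s for s in self.values.index if s in set(ids)]  # preserve order
        return NPXDataset(
            values=self.values.loc[ids].copy(),
            lod=self.lod.copy(),
            batch=self.batch.loc[ids].copy(),
            qc_pass=self.qc_pass.loc[ids].copy(),
            below_lod=self.below_lod.loc[ids].copy(),
        )

    def select_proteins(self, names: Iterable[str]) -> "NPXDataset":
        keep = [p for p in self.values.columns if p in set(names)]
        lod = (
            self.lod[keep].copy()
            if isinstance(self.lod, pd.DataFrame)
            else self.lod.loc[keep].copy()
        )
        return NPXDataset(
            values=self.values[keep].copy(),
            lod=lod,
            batch=self.batch.copy(),
            qc_pass=self.qc_pass.copy(),
            below_lod=self.below_lod[keep].copy(),
        )

    def copy(self) -> "NPXDataset":
        return NPXDataset(
            values=self.values.copy(),
            lod=self.lod.copy(),
            batch=self.batch.copy(),
            qc_pass=self.qc_pass.copy(),
            below_lod=self.below_lod.copy(),
        )

    def equals(self, other: "NPXDataset") -> bool:
        lod_eq = (
            self.lod.round(12).equals(other.lod.round(12))
            if type(self.lod) is type(other.lod)
            else False
        )
        return (
            self.values.round(12).equals(other.values.round(12))
            and lod_eq
            and self.batch.equals(other.batch)
            and self.qc_pass.equals(other.qc_pass)
            and self.below_lod.equals(other.below_lod)
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and normalize dtypes.

    The index must hold unique sample ids; required columns are
    ``METADATA_COLUMNS``. Diagnosis must be one of CD/UC/IBD-U/HC and ages
    must be adult (>= 18).
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    bad_dx = set(meta["Diagnosis"].dropna()) - {"CD", "UC", "IBD-U", "HC"}
    if bad_dx:
        raise ValueError(f"unknown diagnosis values: {sorted(bad_dx)}")
    if (meta["Age"].dropna() < 18).any():
        raise ValueError("adult cohort expected: ages < 18 present")
    meta = meta.copy()
    meta["PriorSurgery"] = meta["PriorSurgery"].astype(bool)
    meta["TreatmentNaive"] = meta["TreatmentNaive"].astype(bool)
    return meta
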