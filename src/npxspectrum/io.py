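"""Readers and writers for long-format NPX tables and metadata CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import METADATA_COLUMNS, NPXDataset, validate_metadata

__all__ = [
    "read_npx_long",
    "write_npx_long",
    "read_metadata",
    "write_metadata",
    "write_npx_wide",
]

NPX_LONG_COLUMNS = ["SampleID", "Assay", "NPX", "LOD", "PlateID", "QC_Warning"]


def read_npx_long(path: str | Path) -> NPXDataset:
    """Read a long-format NPX CSV into an :class:`NPXDataset`.

    Required columns: SampleID, Assay, NPX, LOD, PlateID, QC_Warning.
    QC_Warning is per sample ("PASS"/"WARN"); the below-LOD mask is
    computed as NPX strictly less than LOD. Missing (sample, assay)
    pairs become NaN.
    """
    long = pd.read_csv(path, dtype={"SampleID": str, "Assay": str, "PlateID": str})
    missing = [c for c in NPX_LONG_COLUMNS if c not in long.columns]
    if missing:
        raise ValueError(f"NPX table missing required columns: {missing}")
    for col in ("NPX", "LOD"):
        if not pd.api.types.is_numeric_dtype(long[col]):
            raise ValueError(f"column {col} must be numeric")
    dup = long.duplicated(subset=["SampleID", "Assay"])
    if dup.any():
        pairs = long.loc[dup, ["SampleID", "Assay"]].head(5).to_records(index=False)
        raise ValueError(f"duplicate (SampleID, Assay) pairs, e.g. {list(pairs)}")

    sample_order = long["SampleID"].drop_duplicates().tolist()
    assay_order = long["Assay"].drop_duplicates().tolist()
    values = (
        long.pivot(index="SampleID", columns="Assay", values="NPX")
        .reindex(index=sample_order, columns=assay_order)
    )
    lod = (
        long.groupby("Assay")["LOD"].first().reindex(assay_order).astype(float)
    )
    per_sample = long.drop_duplicates(subset="SampleID").set_index("SampleID")
    batch = per_sample["PlateID"].reindex(sample_order)
    qc_pass = (
        per_sample["QC_Warning"].astype(str).str.upper().ne("WARN").reindex(sample_order)
    )
    below = values.lt(lod, axis=1)
    return NPXDataset(values=values, lod=lod, batch=batch, qc_pass=qc_pass, below_lod=below)


def write_npx_long(ds: NPXDataset, path: str | Path) -> None:
    """Write a dataset to the long CSV dialect read by :func:`read_npx_long`.

    Per-batch LODs (post batch-adjustment) are emitted per sample row.
    """
    lod_matrix = ds.lod_for_samples()
    long = ds.values.stack(future_stack=True).rename("NPX").reset_index()
    long.columns = ["SampleID", "Assay", "NPX"]
    long["LOD"] = lod_matrix.stack(future_stack=True).to_numpy()
    long["PlateID"] = ds.batch.reindex(long["SampleID"]).to_numpy()
    long["QC_Warning"] = np.where(
        ds.qc_pass.reindex(long["SampleID"]).to_numpy(), "PASS", "WARN"
    )
    long = long.dropna(subset=["NPX"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    long.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"SampleID": str}).set_index("SampleID")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, index_label="SampleID")


def write_npx_wide(ds: NPXDataset, path: str | Path) -> None:
    """Export the samples x proteins matrix as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.values.to_csv(path, sep="\t", index_label="SampleID")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
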