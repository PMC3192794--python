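"""Cohort and atlas file I/O.

Cohort tables travel as CSV with the fixed header ``subject_id, group, age,
gender, icv, total_gm_volume, pain_duration, pain_intensity, bdi, bai, mqs,
roi_001, ...``; missing pain fields (healthy subjects) are empty cells.
Atlases travel as TSV with columns ``roi_id, name, hemisphere, ba_label,
x_mm, y_mm, z_mm``. Group labels are canonicalized on read
(case/whitespace-insensitive); malformed files are rejected with row/column
diagnostics.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import ROIAtlas, canonical_group

_META_COLS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "icv",
    "total_gm_volume",
    "pain_duration",
    "pain_intensity",
    "bdi",
    "bai",
    "mqs",
]

_NUMERIC_META = ["age", "icv", "total_gm_volume", "pain_duration",
                 "pain_intensity", "bdi", "bai", "mqs"]


def write_cohort(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cohort table as CSV (full float precision, lossless round-trip)."""
    missing = [c for c in _META_COLS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    roi_cols = [c for c in cohort.columns if c.startswith("roi_")]
    cohort[_META_COLS + roi_cols].to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | os.PathLike, n_rois: int | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Checks the header, canonicalizes group labels, coerces densities to
    float (naming the offending row and column on failure) and verifies
    densities lie in (0, 1). If ``n_rois`` is given, the expected density
    columns ``roi_001 .. roi_{n}`` must all be present.
    """
    raw = pd.read_csv(path, dtype={"subject_id": str, "group": str, "gender": str})
    missing = [c for c in _META_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    roi_cols = [c for c in raw.columns if c.startswith("roi_")]
    if n_rois is not None:
        expected = [f"roi_{i:03d}" for i in range(1, n_rois + 1)]
        absent = [c for c in expected if c not in raw.columns]
        if absent:
            raise ValueError(f"cohort file {path} missing density columns: {absent}")
        roi_cols = expected
    if not roi_cols:
        raise ValueError(f"cohort file {path} has no roi_* density columns")
    try:
        raw["group"] = [canonical_group(g) for g in raw["group"]]
    except ValueError as exc:
        raise ValueError(f"cohort file {path}: {exc}") from exc
    for col in _NUMERIC_META + roi_cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"cohort file {path}: non-numeric value {raw[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        raw[col] = coerced
    dens = raw[roi_cols].to_numpy(dtype=float)
    if np.isnan(dens).any():
        i, j = map(int, np.argwhere(np.isnan(dens))[0])
        raise ValueError(
            f"cohort file {path}: missing density in column {roi_cols[j]!r}, row {i}"
        )
    if (dens <= 0).any() or (dens >= 1).any():
        i, j = map(int, np.argwhere((dens <= 0) | (dens >= 1))[0])
        raise ValueError(
            f"cohort file {path}: density out of (0, 1) in column {roi_cols[j]!r}, row {i}"
        )
    healthy = raw["group"] == "healthy"
    if raw.loc[healthy, "pain_duration"].notna().any():
        raise ValueError(f"cohort file {path}: healthy subjects must not have pain_duration")
    if raw.loc[~healthy, "pain_duration"].isna().any():
        raise ValueError(f"cohort file {path}: patient rows missing pain_duration")
    return raw[_META_COLS + roi_cols]


def write_atlas(atlas: ROIAtlas, path: str | os.PathLike) -> None:
    """Write an atlas as TSV."""
    atlas.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_atlas(path: str | os.PathLike) -> ROIAtlas:
    """Read an atlas TSV; structural validation happens in :class:`ROIAtlas`."""
    table = pd.read_csv(path, sep="\t")
    for col in ("x_mm", "y_mm", "z_mm"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="raise")
    return ROIAtlas(table)
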