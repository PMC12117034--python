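"""Lung densitometry: first-order HU statistics inside a lung mask.

A planning CT stores tissue density in Hounsfield units (HU) — a linear
rescaling of X-ray attenuation with distilled water at 0 HU and air at
-1000 HU. Aerated lung parenchyma sits strongly negative; fibrotic or
consolidated tissue is denser and therefore less negative. Restricted to a
binary lung mask, five first-order statistics summarise one lung:

* ``hu_min``, ``hu_max``, ``hu_mean`` — extremes and mean of the masked HU
  values;
* ``hu_sd`` — their sample standard deviation (``ddof=1``), a measure of
  tissue heterogeneity;
* ``volume_cm3`` — foreground voxel count x voxel volume (mm^3) / 1000.

The module also owns the file formats involved: NIfTI for volumes and masks
(via nibabel) and a canonical CSV schema for per-patient feature tables.
The mask defines the region of interest; the module is agnostic to which
lung (or how much of it) the mask covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ExtractionError, SchemaError

__all__ = [
    "FEATURE_COLUMNS",
    "REQUIRED_COLUMNS",
    "HUVolume",
    "LungMask",
    "LungFeatureRecord",
    "extract_features",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
    "records_to_table",
    "table_to_records",
]

#: The five densitometry features, in canonical column order.
FEATURE_COLUMNS = ["volume_cm3", "hu_min", "hu_max", "hu_mean", "hu_sd"]

#: Columns a feature-table CSV must provide (``rili`` is optional).
REQUIRED_COLUMNS = ["patient_id", *FEATURE_COLUMNS]


@dataclass(frozen=True)
class HUVolume:
    """A 3-D grid of HU values with voxel spacing in mm per axis."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"HU volume must be 3-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("HU volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals (mm), got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return math.prod(self.spacing)


@dataclass(frozen=True)
class LungMask:
    """A binary 3-D grid congruent with its :class:`HUVolume`."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {values.shape}")
        object.__setattr__(self, "values", values > 0)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class LungFeatureRecord:
    """One patient's five densitometry features plus an optional RILI label.

    Invariants (checked on construction): ``hu_min <= hu_mean <= hu_max``,
    ``hu_sd >= 0`` and ``volume_cm3 > 0``. ``rili`` is 1 for patients with
    radiologically visible radiation-induced lung injury, 0 otherwise, or
    ``None`` when unlabelled.
    """

    patient_id: str
    volume_cm3: float
    hu_min: float
    hu_max: float
    hu_mean: float
    hu_sd: float
    rili: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.volume_cm3 = float(self.volume_cm3)
        self.hu_min = float(self.hu_min)
        self.hu_max = float(self.hu_max)
        self.hu_mean = float(self.hu_mean)
        self.hu_sd = float(self.hu_sd)
        if self.rili is not None:
            rili = int(self.rili)
            if rili not in (0, 1):
                raise ValueError(f"rili label must be 0 or 1, got {self.rili}")
            self.rili = rili
        if self.volume_cm3 <= 0:
            raise ValueError(f"{self.patient_id}: volume_cm3 must be > 0, got {self.volume_cm3}")
        if self.hu_sd < 0:
            raise ValueError(f"{self.patient_id}: hu_sd must be >= 0, got {self.hu_sd}")
        if not (self.hu_min <= self.hu_mean <= self.hu_max):
            raise ValueError(
                f"{self.patient_id}: need hu_min <= hu_mean <= hu_max, got "
                f"({self.hu_min}, {self.hu_mean}, {self.hu_max})"
            )

    def replace(self, **changes) -> "LungFeatureRecord":
        return replace(self, **changes)


def extract_features(
    volume: HUVolume, mask: LungMask, patient_id: str = "", rili: int | None = None
) -> LungFeatureRecord:
    """Compute the five densitometry features over the masked voxels.

    ``hu_sd`` uses the sample (n-1) convention; ``volume_cm3`` is foreground
    voxel count x voxel volume in mm^3 divided by 1000.

    Raises
    ------
    ExtractionError
        If shapes differ or the mask has fewer than two foreground voxels
        (the sample SD is undefined on a single voxel).
    """
    if volume.values.shape != mask.values.shape:
        raise ExtractionError(
            f"volume shape {volume.values.shape} != mask shape {mask.values.shape}"
        )
    voxels = volume.values[mask.values]
    if voxels.size == 0:
        raise ExtractionError("empty mask: no foreground voxels to extract from")
    if voxels.size < 2:
        raise ExtractionError("mask must contain >= 2 foreground voxels")
    return LungFeatureRecord(
        patient_id=patient_id,
        volume_cm3=voxels.size * volume.voxel_volume_mm3 / 1000.0,
        hu_min=float(voxels.min()),
        hu_max=float(voxels.max()),
        hu_mean=float(voxels.mean()),
        hu_sd=float(voxels.std(ddof=1)),
        rili=rili,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise SchemaError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise SchemaError(f"{path}: expected a 3-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise SchemaError(f"{path}: missing or non-positive voxel spacing {spacing}")
    return np.asarray(data, dtype=float), spacing


def read_volume(path: str | Path) -> HUVolume:
    """Read a NIfTI CT volume; HU values and mm spacing come from the header."""
    data, spacing = _load_nifti(path)
    return HUVolume(values=data, spacing=spacing)


def read_mask(path: str | Path) -> LungMask:
    """Read a NIfTI mask, binarised at > 0."""
    data, _ = _load_nifti(path)
    return LungMask(values=data > 0)


def write_volume(volume: HUVolume, path: str | Path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), affine), str(path))


def write_mask(mask: LungMask, spacing: tuple[float, float, float], path: str | Path) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Feature-table CSV I/O


def records_to_table(records: list[LungFeatureRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            **{c: getattr(r, c) for c in FEATURE_COLUMNS},
        }
        if r.rili is not None:
            row["rili"] = r.rili
        rows.append(row)
    columns = REQUIRED_COLUMNS + (["rili"] if rows and "rili" in rows[0] else [])
    return pd.DataFrame(rows, columns=columns)


def table_to_records(table: pd.DataFrame) -> list[LungFeatureRecord]:
    has_rili = "rili" in table.columns
    return [
        LungFeatureRecord(
            patient_id=str(row["patient_id"]),
            rili=None if not has_rili or pd.isna(row["rili"]) else int(row["rili"]),
            **{c: row[c] for c in FEATURE_COLUMNS},
        )
        for _, row in table.iterrows()
    ]


def _validate_table(table: pd.DataFrame, source: str = "feature table") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    out = table.copy()
    for col in FEATURE_COLUMNS:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{source}: non-numeric value {out[col].iloc[idx]!r} in column "
                f"{col!r} at row {idx}"
            )
        if coerced.isna().any():
            idx = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SchemaError(f"{source}: missing value in column {col!r} at row {idx}")
        out[col] = coerced.astype(float)
    if "rili" in out.columns:
        rili = pd.to_numeric(out["rili"], errors="coerce")
        if not rili.dropna().isin([0, 1]).all():
            raise SchemaError(f"{source}: rili column must contain only 0/1")
        out["rili"] = rili.astype("Int64")
    bad_order = ~(
        (out["hu_min"] <= out["hu_mean"])
        & (out["hu_mean"] <= out["hu_max"])
        & (out["hu_sd"] >= 0)
        & (out["volume_cm3"] > 0)
    )
    if bad_order.any():
        idx = int(np.flatnonzero(bad_order.to_numpy())[0])
        raise SchemaError(
            f"{source}: record at row {idx} violates "
            "hu_min <= hu_mean <= hu_max, hu_sd >= 0, volume_cm3 > 0"
        )
    return out


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    Unknown columns are preserved. A missing required column raises
    :class:`SchemaError` naming it; a non-numeric feature cell raises with
    the offending row index; invariant violations are rejected at load.
    """
    table = pd.read_csv(path)
    return _validate_table(table, source=str(path))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated feature table as CSV, floats at 6 significant digits."""
    _validate_table(table)
    table.to_csv(path, index=False, float_format="%.6g")
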