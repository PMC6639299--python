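"""Reading, writing and validation of the pipeline's on-disk formats.

Volumes and region-of-interest (ROI) masks travel as NIfTI files; clinical
covariates and survival outcomes travel as plain CSV tables.  Masks must share
the exact voxel grid of their image -- no resampling is ever performed.  Voxel
arrays are indexed 0-based in (slice, row, column) order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

ENDPOINTS = ("DFS", "OS", "DMFS", "LRFS")
LESION_KINDS = ("primary", "lymph_node")

CLINICAL_COLUMNS = [
    "patient_id", "t_stage", "n_stage", "overall_stage", "age", "sex",
    "diagnosis_order",
]
SURVIVAL_COLUMNS = ["patient_id", "endpoint", "time_months", "event"]

OVERALL_STAGES = ("I", "II", "III", "IV")


class AlignmentError(ValueError):
    """Image and mask do not share the same voxel grid."""


class EmptyROIError(ValueError):
    """Mask contains no foreground voxels."""


class TableParseError(ValueError):
    """A clinical or survival CSV row failed validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3-D intensity volume in arbitrary MRI units.

    ``voxels`` is indexed (slice, row, column); ``spacing`` is mm per voxel
    along the same axes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("ImageVolume requires a 3-D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("ImageVolume intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 strictly positive floats")


@dataclass
class ROIMask:
    """A binary region-of-interest on the same grid as its image."""

    voxels: np.ndarray
    lesion_kind: str = "primary"
    patient_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        values = np.unique(arr)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError("mask values must be strictly in {0, 1}")
        self.voxels = arr.astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ValueError("ROIMask requires a 3-D array")
        if self.lesion_kind not in LESION_KINDS:
            raise ValueError(f"lesion_kind must be one of {LESION_KINDS}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class ClinicalRecord:
    patient_id: str
    t_stage: int
    n_stage: int
    overall_stage: str
    age: float
    sex: str
    diagnosis_order: int

    def __post_init__(self) -> None:
        if self.t_stage not in (1, 2, 3, 4):
            raise ValueError(f"t_stage {self.t_stage} out of range 1-4")
        if self.n_stage not in (0, 1, 2, 3):
            raise ValueError(f"n_stage {self.n_stage} out of range 0-3")
        if self.overall_stage not in OVERALL_STAGES:
            raise ValueError(f"overall_stage {self.overall_stage!r} invalid")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex {self.sex!r} invalid")


@dataclass
class SurvivalRecord:
    patient_id: str
    endpoint: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint {self.endpoint!r} not in {ENDPOINTS}")
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError("time must be finite and > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


# ---------------------------------------------------------------------------
# NIfTI volume I/O
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _affine(volume.spacing))
    nib.save(img, str(path))
    return path


def write_mask(mask: ROIMask, path: str | Path,
               spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(spacing))
    nib.save(img, str(path))
    return path


def read_volume_pair(image_path: str | Path, mask_path: str | Path,
                     lesion_kind: str = "primary",
                     patient_id: str = "") -> tuple[ImageVolume, ROIMask]:
    """Load an aligned (image, mask) pair; any nonzero mask voxel becomes 1."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    voxels = np.asanyarray(img.dataobj).astype(float)
    mask_raw = np.asanyarray(msk.dataobj)
    if voxels.shape != mask_raw.shape:
        raise AlignmentError(
            f"image grid {voxels.shape} != mask grid {mask_raw.shape}")
    spacing = tuple(float(abs(z)) for z in img.header.get_zooms()[:3])
    binary = (mask_raw != 0).astype(np.uint8)
    if binary.sum() == 0:
        raise EmptyROIError(f"mask {mask_path} has no foreground voxels")
    volume = ImageVolume(voxels, spacing=spacing, patient_id=patient_id)
    mask = ROIMask(binary, lesion_kind=lesion_kind, patient_id=patient_id)
    return volume, mask


# ---------------------------------------------------------------------------
# Clinical / survival CSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str],
                     path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, CLINICAL_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(ClinicalRecord(
                patient_id=str(row["patient_id"]),
                t_stage=int(row["t_stage"]),
                n_stage=int(row["n_stage"]),
                overall_stage=str(row["overall_stage"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                diagnosis_order=int(row["diagnosis_order"]),
            ))
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_clinical_table(records: Sequence[ClinicalRecord],
                         path: str | Path) -> Path:
    df = pd.DataFrame([{
        "patient_id": r.patient_id, "t_stage": r.t_stage,
        "n_stage": r.n_stage, "overall_stage": r.overall_stage,
        "age": r.age, "sex": r.sex, "diagnosis_order": r.diagnosis_order,
    } for r in records], columns=CLINICAL_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, SURVIVAL_COLUMNS, path)
    records = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        try:
            rec = SurvivalRecord(
                patient_id=str(row["patient_id"]),
                endpoint=str(row["endpoint"]),
                time=float(row["time_months"]),
                event=int(row["event"]),
            )
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}: row {idx}: {exc}") from exc
        key = (rec.patient_id, rec.endpoint)
        if key in seen:
            raise TableParseError(
                f"{path}: row {idx}: duplicate record for {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_survival_table(records: Sequence[SurvivalRecord],
                         path: str | Path) -> Path:
    df = pd.DataFrame([{
        "patient_id": r.patient_id, "endpoint": r.endpoint,
        "time_months": r.time, "event": r.event,
    } for r in records], columns=SURVIVAL_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def survival_frame(records: Sequence[SurvivalRecord],
                   endpoint: str) -> pd.DataFrame:
    """One endpoint's (time, event) as a DataFrame indexed by patient_id."""
    rows = {r.patient_id: (r.time, r.event)
            for r in records if r.endpoint == endpoint}
    if not rows:
        raise ValueError(f"no survival records for endpoint {endpoint!r}")
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["time", "event"])
    df.index.name = "patient_id"
    return df


# ---------------------------------------------------------------------------
# Chronological cohort split
# ---------------------------------------------------------------------------

def split_cohort(records: Sequence[ClinicalRecord],
                 split_fraction: float) -> tuple[list[str], list[str]]:
    """Date-ordered split: earliest ceil(fraction*n) patients go to training.

    Ties in ``diagnosis_order`` are broken by ``patient_id``; duplicate
    (diagnosis_order, patient_id) pairs are rejected so the split is a
    deterministic partition.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie strictly in (0, 1)")
    keys = [(r.diagnosis_order, r.patient_id) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (diagnosis_order, patient_id) pairs")
    n = len(records)
    n_train = math.ceil(split_fraction * n - 1e-9)
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave an empty cohort")
    ordered = sorted(records, key=lambda r: (r.diagnosis_order, r.patient_id))
    training = [r.patient_id for r in ordered[:n_train]]
    validation = [r.patient_id for r in ordered[n_train:]]
    return training, validation
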