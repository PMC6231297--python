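"""Core data types and file IO.

Conventions used throughout the package:

* Volumes are 3D arrays indexed 0-based with axis order ``(x, y, z)``
  where x is the sagittal index, y the coronal index and z the
  transverse index.  Plane definitions follow: transverse = fixed z,
  coronal = fixed y, sagittal = fixed x.
* All volumes of a cohort live on one common grid; a shape mismatch is
  an error, never a resample trigger.
* Diagnostic groups are one of ``GROUP_LABELS``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

GROUP_LABELS = ("AD", "NC", "MCIc", "MCInc", "MCIun")

#: plausible age bounds (years) enforced on subject records
AGE_BOUNDS = (40.0, 110.0)


@dataclasses.dataclass
class BrainVolume:
    """A 3D intensity volume on the common template grid."""

    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got {self.data.ndim}D for '{self.subject_id}'"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"volume shape must be strictly positive: {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"volume '{self.subject_id}' contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclasses.dataclass
class HippocampusMask:
    """Binary mask marking left/right hippocampal regions."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {data.ndim}D")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        if not data.any():
            raise ValueError("mask has no nonzero voxel")
        self.data = data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass
class SubjectRecord:
    """One subject: id, diagnostic group, age and optional features."""

    subject_id: str
    group: str
    age: float
    structural_features: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group '{self.group}' for subject '{self.subject_id}'; "
                f"expected one of {GROUP_LABELS}"
            )
        self.age = float(self.age)
        if not (AGE_BOUNDS[0] <= self.age <= AGE_BOUNDS[1]):
            raise ValueError(
                f"age {self.age} outside plausible range {AGE_BOUNDS} "
                f"for subject '{self.subject_id}'"
            )
        if self.structural_features is not None:
            self.structural_features = np.asarray(self.structural_features, dtype=float)


@dataclasses.dataclass
class FeatureMatrix:
    """A (n_subjects x n_features) matrix with row/column labels."""

    values: np.ndarray
    subject_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError(
                f"row count {self.values.shape[0]} != id count {len(self.subject_ids)}"
            )
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"column count {self.values.shape[1]} != "
                f"name count {len(self.feature_names)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# volumes / masks


def read_volume(path: str | Path, subject_id: str | None = None) -> BrainVolume:
    """Read a NIfTI volume.

    Raises if the file is missing, not 3D, or holds non-finite voxels.
    Integer inputs round-trip bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path}")
    return BrainVolume(data=data, subject_id=subject_id or path.stem.replace(".nii", ""))


def write_volume(volume: BrainVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with an identity affine."""
    data = volume.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.to_filename(str(path))


def read_mask(path: str | Path) -> HippocampusMask:
    """Read a binary hippocampus mask from NIfTI."""
    vol = read_volume(path)
    return HippocampusMask(data=np.rint(vol.data).astype(np.uint8))


def write_mask(mask: HippocampusMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data, affine=np.eye(4))
    img.to_filename(str(path))


# ---------------------------------------------------------------------------
# subject tables


_REQUIRED_COLUMNS = ("id", "group", "age")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read subjects from CSV with columns ``id, group, age`` (+ optional
    structural feature columns, taken in file order)."""
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"subject table missing required column '{col}'")
    feature_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS and c != "sex"]
    records = []
    for _, row in df.iterrows():
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparsable age '{row['age']}' for id '{row['id']}'") from exc
        feats = row[feature_cols].to_numpy(dtype=float) if feature_cols else None
        records.append(
            SubjectRecord(
                subject_id=str(row["id"]),
                group=str(row["group"]),
                age=age,
                structural_features=feats,
            )
        )
    return records


def write_subject_table(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [{"id": r.subject_id, "group": r.group, "age": r.age} for r in records]
    pd.DataFrame(rows, columns=["id", "group", "age"]).to_csv(path, index=False)


def group_counts(records: Sequence[SubjectRecord]) -> dict[str, int]:
    counts = {g: 0 for g in GROUP_LABELS}
    for r in records:
        counts[r.group] += 1
    return counts


# ---------------------------------------------------------------------------
# feature matrices


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write as CSV: first column ``subject_id``, then one column per feature.

    Values are written at full precision so the round-trip is lossless.
    """
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "subject_id", fm.subject_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature table {path}: {exc}") from exc
    if "subject_id" not in df.columns:
        raise ValueError("feature table must have a 'subject_id' column")
    ids = df["subject_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "subject_id"]
    values = df[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"feature table {path} has missing or non-finite entries")
    return FeatureMatrix(values=values, subject_ids=ids, feature_names=names)
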