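"""Intensity normalization and linear age correction.

Age correction fits, per voxel (or per feature column), an ordinary
least-squares model ``y_m = w_m * age + b_m`` on healthy subjects, then
shifts every subject to a common reference age ``C``::

    y'_mn = w_m * (C - age_n) + y_mn
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from mcipredict.io import BrainVolume, FeatureMatrix, SubjectRecord

DEFAULT_REFERENCE_AGE = 75.0


@dataclasses.dataclass
class AgeCorrectionModel:
    """Per-voxel (or per-feature) slope/intercept and the reference age."""

    slope: np.ndarray
    intercept: np.ndarray
    reference_age: float = DEFAULT_REFERENCE_AGE
    fit_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.slope = np.asarray(self.slope, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        if self.slope.shape != self.intercept.shape:
            raise ValueError("slope and intercept must have the same shape")
        if not np.isfinite(self.reference_age):
            raise ValueError("reference_age must be finite")

    def correction(self, age: float) -> np.ndarray:
        """The additive correction term ``w * (C - age)``."""
        return self.slope * (self.reference_age - float(age))

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            slope=self.slope,
            intercept=self.intercept,
            reference_age=self.reference_age,
        )

    @classmethod
    def load(cls, path) -> "AgeCorrectionModel":
        with np.load(path) as z:
            return cls(
                slope=z["slope"],
                intercept=z["intercept"],
                reference_age=float(z["reference_age"]),
            )


# ---------------------------------------------------------------------------
# histogram matching


def match_histogram(
    subject: BrainVolume, template: BrainVolume, n_anchors: int = 256
) -> BrainVolume:
    """Monotone quantile mapping of subject intensities onto the template's.

    Uses ``n_anchors`` evenly spaced quantile anchor points with linear
    interpolation in between.  Raises on shape mismatch or a
    constant-valued subject volume (degenerate mapping).
    """
    if subject.shape != template.shape:
        raise ValueError(
            f"shape mismatch: subject {subject.shape} vs template {template.shape}"
        )
    src = subject.data.astype(float)
    if np.ptp(src) == 0:
        raise ValueError("subject volume is constant-valued; quantile map is degenerate")
    q = np.linspace(0.0, 1.0, n_anchors)
    src_q = np.quantile(src, q)
    tpl_q = np.quantile(template.data.astype(float), q)
    mapped = np.interp(src.ravel(), src_q, tpl_q).reshape(src.shape)
    return BrainVolume(data=mapped, subject_id=subject.subject_id)


# ---------------------------------------------------------------------------
# voxel-level age correction


def _ols_slopes(Y: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column OLS of Y (n x ...) on ages (n,)."""
    a = ages - ages.mean()
    denom = np.dot(a, a)
    Y_mean = Y.mean(axis=0)
    slope = np.tensordot(a, Y - Y_mean, axes=(0, 0)) / denom
    intercept = Y_mean - slope * ages.mean()
    return slope, intercept


def fit_age_correction(
    healthy_volumes: Sequence[BrainVolume],
    ages: Sequence[float],
    reference_age: float = DEFAULT_REFERENCE_AGE,
    fit_mask: Optional[np.ndarray] = None,
) -> AgeCorrectionModel:
    """Independent OLS fit at every voxel over healthy subjects.

    Requires at least 3 subjects and at least 2 distinct ages; all
    volumes must share one grid.  With ``fit_mask`` given, slopes
    outside the mask are forced to zero (no correction there).
    """
    if len(healthy_volumes) < 3:
        raise ValueError(f"need >= 3 healthy subjects to fit, got {len(healthy_volumes)}")
    ages_arr = np.asarray(ages, dtype=float)
    if len(ages_arr) != len(healthy_volumes):
        raise ValueError("ages and volumes length mismatch")
    if np.unique(ages_arr).size < 2:
        raise ValueError("all ages identical: singular regression")
    shape = healthy_volumes[0].shape
    for v in healthy_volumes:
        if v.shape != shape:
            raise ValueError(f"volume grid mismatch: {v.shape} vs {shape}")

    Y = np.stack([v.data.astype(float) for v in healthy_volumes], axis=0)
    slope, intercept = _ols_slopes(Y, ages_arr)
    if fit_mask is not None:
        fit_mask = np.asarray(fit_mask).astype(bool)
        if fit_mask.shape != shape:
            raise ValueError("fit_mask shape mismatch")
        slope = np.where(fit_mask, slope, 0.0)
        intercept = np.where(fit_mask, intercept, 0.0)
    return AgeCorrectionModel(
        slope=slope, intercept=intercept, reference_age=reference_age, fit_mask=fit_mask
    )


def apply_age_correction(
    model: AgeCorrectionModel, volume: BrainVolume, age: float
) -> BrainVolume:
    """Shift every voxel to the model's reference age."""
    if model.slope.shape != volume.shape:
        raise ValueError(
            f"model grid {model.slope.shape} does not cover volume {volume.shape}"
        )
    corrected = volume.data.astype(float) + model.correction(age)
    return BrainVolume(data=corrected, subject_id=volume.subject_id)


# ---------------------------------------------------------------------------
# feature-level age correction


def fit_feature_age_correction(
    features: FeatureMatrix,
    records: Sequence[SubjectRecord],
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> AgeCorrectionModel:
    """Fit the per-column aging model on the NC rows of ``features``."""
    by_id = {r.subject_id: r for r in records}
    missing = [s for s in features.subject_ids if s not in by_id]
    if missing:
        raise ValueError(f"records missing for subjects: {missing[:5]}")
    groups = np.array([by_id[s].group for s in features.subject_ids])
    ages = np.array([by_id[s].age for s in features.subject_ids], dtype=float)
    nc = groups == "NC"
    if nc.sum() < 3:
        raise ValueError(f"need >= 3 NC rows to fit feature age correction, got {nc.sum()}")
    if np.unique(ages[nc]).size < 2:
        raise ValueError("all NC ages identical: singular regression")
    slope, intercept = _ols_slopes(features.values[nc], ages[nc])
    return AgeCorrectionModel(slope=slope, intercept=intercept, reference_age=reference_age)


def fit_and_apply_feature_age_correction(
    features: FeatureMatrix,
    records: Sequence[SubjectRecord],
    reference_age: float = DEFAULT_REFERENCE_AGE,
) -> FeatureMatrix:
    """Fit on NC rows only, then correct every row to the reference age."""
    model = fit_feature_age_correction(features, records, reference_age)
    by_id = {r.subject_id: r for r in records}
    ages = np.array([by_id[s].age for s in features.subject_ids], dtype=float)
    corrected = features.values + model.slope[None, :] * (reference_age - ages[:, None])
    return FeatureMatrix(
        values=corrected,
        subject_ids=list(features.subject_ids),
        feature_names=list(features.feature_names),
    )
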