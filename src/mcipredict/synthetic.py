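"""Synthetic phantom cohorts for exercising the full pipeline.

Each phantom volume is a smooth background template plus two bright
ellipsoidal "hippocampus" regions.  Disease severity shrinks the bright
region and lowers its mean intensity; normal aging adds a linear
intensity trend inside the region; Gaussian noise is added everywhere.
A matching structural feature table carries group mean shifts in a
designated informative column subset plus an age trend, remaining
columns being pure noise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from mcipredict.io import (
    BrainVolume,
    FeatureMatrix,
    HippocampusMask,
    SubjectRecord,
)

#: relative severity per group, scaling both intensity loss and shrinkage
GROUP_ORDER = ("AD", "NC", "MCIc", "MCInc")

#: group offsets used for structural features, chosen so that the
#: MCIc-vs-MCInc shift equals struct_effect_size in pooled-SD units
STRUCT_GROUP_SHIFT = {"AD": 1.5, "MCIc": 1.0, "MCInc": 0.0, "NC": -0.5, "MCIun": 0.5}


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the phantom generator."""

    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"AD": 20, "NC": 20, "MCIc": 15, "MCInc": 15}
    )
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    atrophy_effect: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"AD": 0.6, "MCIc": 0.4, "MCInc": 0.15, "NC": 0.0}
    )
    age_slope: float = -0.4  # intensity units per year inside hippocampus
    age_range: tuple[float, float] = (55.0, 91.0)
    noise_sd: float = 1.0
    n_struct_features: int = 325
    n_informative: int = 20
    struct_effect_size: float = 1.0
    struct_age_slope: float = 0.05
    severity_jitter: float = 0.0  # per-subject SD of the atrophy severity
    struct_subject_sd: float = 0.0  # per-subject latent shared by informative columns
    reference_age: float = 75.0
    hippocampus_contrast: float = 40.0
    shrink_fraction: float = 0.25  # max relative semi-axis shrinkage at severity 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("subject counts must be non-negative")
        if any(s < 64 for s in self.volume_shape):
            raise ValueError(
                f"volume_shape {self.volume_shape} too small: every dimension "
                "must be >= 64 so that 32x32 patch windows fit"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        a = self.atrophy_effect
        if not (a["AD"] >= a["MCIc"] >= a["MCInc"] >= a["NC"]):
            raise ValueError("atrophy_effect must be monotone AD >= MCIc >= MCInc >= NC")


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = np.zeros(shape, dtype=float)
    for g, c, s in zip(grids, center, semi):
        acc = acc + ((g - c) / s) ** 2
    return acc <= 1.0


def _hippocampus_geometry(shape: tuple[int, int, int]):
    """Centers and semi-axes of the two ellipsoids, scaled to the grid."""
    nx, ny, nz = shape
    cy, cz = ny / 2.0, nz / 2.0
    semi = np.array([0.095 * nx, 0.125 * ny, 0.11 * nz])
    left = np.array([0.375 * nx, cy, cz])
    right = np.array([0.625 * nx, cy, cz])
    return [(left, semi), (right, semi)]


def make_template(shape: tuple[int, int, int], seed: int = 0) -> BrainVolume:
    """Smooth background template (no hippocampal signal, no noise)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=shape)
    smooth = gaussian_filter(base, sigma=min(shape) / 8.0)
    smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    data = 100.0 + 10.0 * smooth
    return BrainVolume(data=data.astype(np.float32), subject_id="template")


def make_mask(shape: tuple[int, int, int]) -> HippocampusMask:
    """Cohort-level hippocampus mask: union of the two ellipsoids."""
    data = np.zeros(shape, dtype=np.uint8)
    for center, semi in _hippocampus_geometry(shape):
        data |= _ellipsoid(shape, center, semi).astype(np.uint8)
    return HippocampusMask(data=data)


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[SubjectRecord], list[BrainVolume], HippocampusMask]:
    """Generate subjects, volumes and the shared hippocampus mask.

    Deterministic given ``cfg.seed``.  Inside the (possibly shrunken)
    hippocampal region the intensity is::

        background + contrast * (1 - atrophy) + age_slope * (age - C)

    and Gaussian noise of scale ``noise_sd`` is added everywhere.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.volume_shape
    template = make_template(shape, seed=cfg.seed)
    mask = make_mask(shape)
    geometry = _hippocampus_geometry(shape)

    records: list[SubjectRecord] = []
    volumes: list[BrainVolume] = []
    counter = 0
    for group in GROUP_ORDER:
        n = cfg.n_per_group.get(group, 0)
        severity = cfg.atrophy_effect.get(group, 0.0)
        for _ in range(n):
            subject_id = f"S{counter:04d}"
            counter += 1
            age = float(rng.uniform(*cfg.age_range))
            records.append(SubjectRecord(subject_id=subject_id, group=group, age=age))

            subj_severity = severity
            if cfg.severity_jitter > 0:
                subj_severity = float(
                    np.clip(severity + rng.normal(0.0, cfg.severity_jitter), 0.0, 1.0)
                )
            vol = template.data.astype(np.float64).copy()
            scale = 1.0 - cfg.shrink_fraction * subj_severity
            signal = np.zeros(shape, dtype=bool)
            for center, semi in geometry:
                signal |= _ellipsoid(shape, center, semi * scale)
            delta = cfg.hippocampus_contrast * (1.0 - subj_severity)
            delta += cfg.age_slope * (age - cfg.reference_age)
            vol[signal] += delta
            if cfg.noise_sd > 0:
                vol += rng.normal(0.0, cfg.noise_sd, size=shape)
            volumes.append(
                BrainVolume(data=vol.astype(np.float32), subject_id=subject_id)
            )
    return records, volumes, mask


def generate_structural_features(
    cfg: SyntheticConfig, records: Sequence[SubjectRecord]
) -> FeatureMatrix:
    """Structural feature table matching ``records``.

    The first ``cfg.n_informative`` columns carry a group mean shift of
    ``struct_effect_size`` (in units of the unit noise SD, between the
    MCIc and MCInc groups) plus a linear age trend; the remaining
    columns are pure standard normal noise.  Deterministic given seed.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n, f = len(records), cfg.n_struct_features
    values = rng.normal(0.0, 1.0, size=(n, f))
    n_info = min(cfg.n_informative, f)
    for i, rec in enumerate(records):
        shift = cfg.struct_effect_size * STRUCT_GROUP_SHIFT[rec.group]
        trend = cfg.struct_age_slope * (rec.age - cfg.reference_age)
        latent = rng.normal(0.0, cfg.struct_subject_sd) if cfg.struct_subject_sd > 0 else 0.0
        values[i, :n_info] += shift + trend + latent
    names = [f"info_{j}" if j < n_info else f"noise_{j}" for j in range(f)]
    return FeatureMatrix(
        values=values,
        subject_ids=[r.subject_id for r in records],
        feature_names=names,
    )
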