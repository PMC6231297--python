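"""Hippocampus-constrained sampling of 2.5D tri-planar patches.

A 2.5D patch stacks three orthogonal 32x32 slices centered at one voxel
as three channels: channel 0 = transverse (fixed z, spanning x/y),
channel 1 = coronal (fixed y, spanning x/z), channel 2 = sagittal
(fixed x, spanning y/z).  For the even window size 32 the center voxel
sits at index 16, i.e. the window spans ``[c - 16, c + 15]``.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

from mcipredict.io import BrainVolume, HippocampusMask

PATCH_SIZE = 32
HALF = PATCH_SIZE // 2  # center index within the window

DEFAULT_N_LOCATIONS = 151
DEFAULT_MIN_DISTANCE = 2.0
DEFAULT_MAX_DRAWS = 10_000


class PatchLocation(NamedTuple):
    x: int
    y: int
    z: int


@dataclasses.dataclass
class Patch25D:
    """32x32x3 tri-planar patch centered at one voxel."""

    data: np.ndarray
    center: PatchLocation
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}x3, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("patch contains non-finite values")


def window_fits(shape: Sequence[int], loc: PatchLocation) -> bool:
    """True if all three 32x32 windows centered at ``loc`` fit in bounds."""
    return all(HALF <= c <= s - HALF for c, s in zip(loc, shape))


def valid_center_mask(mask: HippocampusMask) -> np.ndarray:
    """In-mask voxels whose patch windows fit inside the grid."""
    valid = mask.data.astype(bool).copy()
    for axis, size in enumerate(mask.shape):
        idx = np.arange(size)
        ok = (idx >= HALF) & (idx <= size - HALF)
        shape = [1, 1, 1]
        shape[axis] = size
        valid &= ok.reshape(shape)
    return valid


def sample_locations(
    mask: HippocampusMask,
    n: int = DEFAULT_N_LOCATIONS,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    seed: int = 0,
    max_draws: int = DEFAULT_MAX_DRAWS,
) -> list[PatchLocation]:
    """Randomly draw ``n`` in-mask centers, pairwise Euclidean distance
    strictly greater than ``min_distance``.

    Rejection sampling, deterministic for a given seed.  The same
    location list is meant to be reused for every subject of an
    experiment.  Raises if the budget of ``max_draws`` draws is spent
    before ``n`` locations are accepted.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    candidates = np.argwhere(valid_center_mask(mask))
    if len(candidates) < n:
        raise ValueError(
            f"mask has only {len(candidates)} window-fitting voxels, need {n}"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, 3), dtype=float)
    out: list[PatchLocation] = []
    draws = 0
    while len(out) < n:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not place {n} locations at min_distance {min_distance} "
                f"within {max_draws} draws ({len(out)} placed); mask too small"
            )
        c = candidates[rng.integers(len(candidates))]
        draws += 1
        if len(out) and np.min(np.sum((accepted - c) ** 2, axis=1)) <= min_distance**2:
            continue
        accepted = np.vstack([accepted, c.astype(float)])
        out.append(PatchLocation(int(c[0]), int(c[1]), int(c[2])))
    return out


def extract_patch(volume: BrainVolume, loc: PatchLocation) -> Patch25D:
    """Cut the three orthogonal windows centered at ``loc``; values are
    copied untransformed."""
    if not window_fits(volume.shape, loc):
        raise ValueError(f"patch window at {loc} out of bounds for volume {volume.shape}")
    x, y, z = loc
    v = volume.data
    transverse = v[x - HALF : x + HALF, y - HALF : y + HALF, z]
    coronal = v[x - HALF : x + HALF, y, z - HALF : z + HALF]
    sagittal = v[x, y - HALF : y + HALF, z - HALF : z + HALF]
    data = np.stack([transverse, coronal, sagittal], axis=-1).astype(np.float32)
    return Patch25D(data=data, center=loc, subject_id=volume.subject_id)


def extract_patch_set(
    volume: BrainVolume, locs: Sequence[PatchLocation]
) -> list[Patch25D]:
    """One patch per location, order preserved."""
    return [extract_patch(volume, loc) for loc in locs]


def locations_to_csv(locs: Sequence[PatchLocation], path) -> None:
    arr = np.array([[l.x, l.y, l.z] for l in locs], dtype=int)
    np.savetxt(path, arr, fmt="%d", delimiter=",", header="x,y,z", comments="")


def locations_from_csv(path) -> list[PatchLocation]:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, dtype=int, ndmin=2)
    return [PatchLocation(int(r[0]), int(r[1]), int(r[2])) for r in arr]
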