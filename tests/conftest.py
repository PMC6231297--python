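"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from mcipredict.synthetic import SyntheticConfig, generate_cohort, make_mask


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_per_group={"AD": 6, "NC": 6, "MCIc": 6, "MCInc": 6},
        noise_sd=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(records, volumes, mask) — 24 subjects at 64^3, reused read-only."""
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def default_mask():
    return make_mask((64, 64, 64))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def assert_axis_convention(volume_data: np.ndarray) -> None:
    """Shared assertion: axis order is (x=sagittal, y=coronal, z=transverse)."""
    assert volume_data.ndim == 3
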