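"""Shared fixtures: synthetic datasets at full and reduced scale."""

from __future__ import annotations

import numpy as np
import pytest

from nirmold import (
    GeneratorConfig,
    MCCVPlan,
    generate_dataset,
    kennard_stone_split,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default high-SNR two-class dataset (511 points, 200 per class) + mask."""
    data, mask = generate_dataset(GeneratorConfig(seed=0))
    return data, mask


@pytest.fixture(scope="session")
def default_split(default_dataset):
    """Kennard-Stone 2:1 split of the default dataset (cal, test, mask)."""
    data, mask = default_dataset
    split = kennard_stone_split(data.absorbance, 2.0 / 3.0)
    cal = data.subset(split.calibration_indices, role="calibration")
    test = data.subset(split.test_indices, role="test")
    return cal, test, mask


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale dataset (150-point grid, 40 per class) for fast tests."""
    cfg = GeneratorConfig(grid=(890.0, 1720.0, 150), n_per_class=40, seed=7)
    data, mask = generate_dataset(cfg)
    return data, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_plan():
    return MCCVPlan(n_iterations=30, holdout_fraction=0.25, seed=5)
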