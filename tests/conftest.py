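from __future__ import annotations

import numpy as np
import pytest

from survscan import (
    ScenarioConfig,
    SubjectRecord,
    generate_grid_geography,
    plant_true_cluster,
)


@pytest.fixture(scope="session")
def grid8():
    return generate_grid_geography(8, 8, 1.0)


@pytest.fixture(scope="session")
def model_a_truth(grid8):
    """6-region circular planted cluster near the grid center (~10% of regions)."""
    return plant_true_cluster(grid8, "circular", target_fraction=6 / 64, seed_region=27)


@pytest.fixture()
def model_a_config(grid8, model_a_truth):
    return ScenarioConfig(
        area=grid8,
        truth=[model_a_truth],
        n_subjects=1000,
        mean_in=5.0,
        mean_out=10.0,
        censoring_rate=0.1,
        window_mode="circular",
        B=199,
        seed=11,
    )


def make_subjects(regions, times, censored=None):
    if censored is None:
        censored = [False] * len(regions)
    return [
        SubjectRecord(int(r), float(t), bool(c))
        for r, t, c in zip(regions, times, censored)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
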