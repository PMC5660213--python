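"""Shared fixtures.

The expensive fixture is ``benchmark_runs``: the five seeded training runs of
the standard synthetic benchmark (20 families x 8 members at 128 px), shared
across the dereplication-performance, novel-category and noise-robustness
tests so each network is trained exactly once per session.
"""

import numpy as np
import pytest

from hsqcnet import (
    AxisCalibration,
    PerturbationModel,
    SiameseSpectralModel,
)
from hsqcnet.training import benchmark_training_config


@pytest.fixture(scope="session")
def cal_small() -> AxisCalibration:
    """Standard window at a 64-px raster (fast unit-test scale)."""
    return AxisCalibration.default(64)


@pytest.fixture(scope="session")
def tiny_model() -> SiameseSpectralModel:
    """A 4-family x 5-member dataset at 48 px for fast training tests."""
    return SiameseSpectralModel.from_synthetic(
        n_families=4, members=5, input_side=48, seed=11,
        perturbation=PerturbationModel(salt_pepper_rate=0.005),
    )


@pytest.fixture(scope="session")
def benchmark_runs():
    """The five seeded benchmark training runs (shared; ~3-4 min per seed).

    Each entry is (model, results) for seeds 0..4 of the standard synthetic
    benchmark with the frozen training configuration.
    """
    runs = []
    for seed in range(5):
        model = SiameseSpectralModel.from_synthetic(seed=seed)
        res = model.fit(benchmark_training_config(seed=seed))
        runs.append((model, res))
    return runs


def brute_force_ranking(corpus_coords, corpus_ids, query_coord):
    """Reference neighbour ranking: distance ascending, then id ascending."""
    d = np.sqrt(((corpus_coords - query_coord) ** 2).sum(axis=1))
    order = sorted(range(len(corpus_ids)), key=lambda j: (d[j], corpus_ids[j]))
    return np.array(order), d
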