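"""Shared fixtures: tiny synthetic cohorts and reduced pipeline grids.

Everything is generated at run time from seeded generators; session scope
keeps the more expensive cohorts shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from wvgerp import CohortSpec, PipelineConfig, generate_cohort


#: Small channel/band grid used where the full 540-graph grid is overkill.
SMALL_CHANNELS = ("Fz", "Pz", "Cz")
SMALL_BANDS = ("raw", "delta")


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(channels=SMALL_CHANNELS, bands=SMALL_BANDS)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 + 4 subjects, strong effect, low noise, few trials: fast end-to-end."""
    spec = CohortSpec(n_per_group=4, n_trials=8, effect_size=0.8,
                      noise_sd=1.0, seed=11)
    subjects, labels = generate_cohort(spec)
    return spec, subjects, labels


@pytest.fixture(scope="session")
def one_subject():
    """A single default-geometry subject (15 channels, 72 trials)."""
    spec = CohortSpec(n_per_group=2, seed=7)
    subjects, labels = generate_cohort(spec)
    return spec, subjects[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
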