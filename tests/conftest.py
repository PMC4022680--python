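"""Shared fixtures: study-grid batches are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from fissim.engine import run_batch, study_conditions

#: base seed for the session's study-grid sweeps
BASE_SEED = 20140515


@pytest.fixture(scope="session")
def grid_batch_n10():
    """Full study grid for groups of 10 (9 ratios x 10 transfers), 100
    seeded replicates per condition."""
    return run_batch(study_conditions(n_values=[10]), reps=100, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def grid_batch_n20():
    """Full study grid for groups of 20, 100 seeded replicates per condition."""
    return run_batch(study_conditions(n_values=[20]), reps=100, base_seed=BASE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
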