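import numpy as np
import pytest

import landmarklab as ll


@pytest.fixture(scope="session")
def default_offsets() -> np.ndarray:
    return np.arange(-48, 49, 6, dtype=float)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject cohort with trials, shared across tests (seeded)."""
    cfg = ll.CohortConfig(n_subjects=6, seed=20240917)
    observers = ll.draw_cohort(cfg)
    trials = ll.simulate_trials(observers, cfg)
    return cfg, observers, trials


@pytest.fixture(scope="session")
def small_fits(small_cohort):
    _, _, trials = small_cohort
    return ll.fit_blocks(trials)
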