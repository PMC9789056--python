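import numpy as np
import pytest

from gutdyn import SimConfig, simulate_cohort

BASE_MONTH = 2016 * 12 + 10  # Oct 2016


@pytest.fixture(scope="session")
def small_cohort():
    """3 individuals, 40 taxa, schedules spanning all interval groups."""
    months = [
        [BASE_MONTH + m for m in (0, 1, 2, 3, 9, 14, 20, 26, 32)],
        [BASE_MONTH + m for m in (0, 1, 2, 7, 13, 19, 25, 31, 37)],
        [BASE_MONTH + m for m in (1, 2, 3, 4, 10, 16, 22, 28, 40)],
    ]
    cfg = SimConfig(
        n_individuals=3, n_taxa=40, months=months, drift_sd=0.1,
        bloom_prob=0.1, retention_decay=0.02, seq_depth=3000, rng_seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
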