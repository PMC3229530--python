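import logging

import numpy as np
import pandas as pd
import pytest

from tzdcohort import ScenarioConfig, simulate

logging.getLogger("tzdcohort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(n_patients=1500, n_practices=15, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config):
    """One modest synthetic dataset shared across read-only tests."""
    return simulate(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_prescription_stream(rng, n_max=12, span=2000):
    """A random (possibly empty, unordered, duplicated) Rx day stream."""
    n = rng.integers(0, n_max + 1)
    days = rng.integers(0, span, size=n)
    if n and rng.random() < 0.3:  # inject duplicates
        days = np.concatenate([days, days[: max(1, n // 2)]])
    return days


def day_loop_state(rx_days, day):
    """Brute-force exposure state: scan the raw stream day by day."""
    past_rx = [r for r in rx_days if r <= day]
    if not past_rx:
        return "never"
    dt = day - max(past_rx)
    if dt < 91:
        return "current"
    if dt < 365:
        return "recent"
    return "past"
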