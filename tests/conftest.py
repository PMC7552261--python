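import numpy as np
import pandas as pd
import pytest

from pantsense.simulate import HerdScenario, simulate_herd


@pytest.fixture(scope="session")
def tiny_sim():
    """A small but complete synthetic herd (12 animals, 1 day)."""
    scenario = HerdScenario(n_animals=12, days=1, seed=123)
    return simulate_herd(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_observed(records):
    """Observer minute frame from (animal_id, minute_offset, state, ps)."""
    base = pd.Timestamp("2019-01-10 08:00")
    return pd.DataFrame(
        {
            "animal_id": [r[0] for r in records],
            "minute": [base + pd.Timedelta(minutes=r[1]) for r in records],
            "state": np.array([r[2] for r in records], dtype=np.int8),
            "ps": pd.array([r[3] for r in records], dtype="Int8"),
        }
    )


def make_sensor(records):
    """Sensor minute frame from (animal_id, minute_offset, state)."""
    base = pd.Timestamp("2019-01-10 08:00")
    return pd.DataFrame(
        {
            "animal_id": [r[0] for r in records],
            "minute": [base + pd.Timedelta(minutes=r[1]) for r in records],
            "state": np.array([r[2] for r in records], dtype=np.int8),
        }
    )
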