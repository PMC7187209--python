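import numpy as np
import pandas as pd
import pytest

from kmpool import registry_preset, simulate_registry


@pytest.fixture(scope="session")
def small_ipd():
    """12 records, distinct times, mixed events: a hand-checkable Cox fixture."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.5, 4.0, 5.5, 6.0, 7.5, 8.0, 9.5, 10.0, 11.5, 12.0],
            "event": [1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1],
            "treat": [1.0, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
        }
    )


@pytest.fixture(scope="session")
def tied_ipd():
    """16 records with heavy ties, exercising the Efron correction."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "time": rng.integers(1, 5, 16).astype(float),
            "event": rng.integers(0, 2, 16),
            "treat": np.tile([0.0, 1.0], 8),
        }
    )


@pytest.fixture(scope="session")
def ncr_like_cohort():
    """One registry-preset cohort (n=1,947) reused across tests."""
    return simulate_registry(registry_preset(seed=7))
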