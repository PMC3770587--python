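import numpy as np
import pandas as pd
import pytest

from breedtrends.io_formats import CBARQ_SCALES, RegistrationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_matrix():
    """Three breeds over 2000-2004: one boom-bust, one monotone, one constant."""
    years = pd.Index(range(2000, 2005), name="year")
    df = pd.DataFrame(
        {
            "boomer": [1.0, 2.0, 100.0, 2.0, 1.0],
            "climber": [1.0, 10.0, 100.0, 1000.0, 10000.0],
            "steady": [50.0, 50.0, 50.0, 50.0, 50.0],
        },
        index=years,
    )
    return RegistrationMatrix(df)


def make_dog_records(breed_sizes: dict[str, int], value: float = 2.0) -> pd.DataFrame:
    """Per-dog records with every scale set to a constant value."""
    rows = []
    i = 0
    for breed, n in breed_sizes.items():
        for _ in range(n):
            rows.append(
                {"dog_id": f"d{i}", "breed": breed}
                | {s: value for s in CBARQ_SCALES}
            )
            i += 1
    return pd.DataFrame(rows)
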