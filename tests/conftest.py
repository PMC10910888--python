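import numpy as np
import pandas as pd
import pytest

from epitransport import (
    DGMParams,
    NINFEA_MARGINS,
    PBR_2019_MARGINS,
    simulate_population,
)
from epitransport.populations import as_education, as_parity

# one base seed for every simulated fixture; substreams are spawned from it
BASE_SEED = 0


@pytest.fixture(scope="session")
def dgm():
    return DGMParams()


@pytest.fixture(scope="session")
def study_small(dgm):
    """Study-margin population at a size where fits are instant."""
    return simulate_population(NINFEA_MARGINS, 3000, np.random.SeedSequence((BASE_SEED, 1)), params=dgm, s=1)


@pytest.fixture(scope="session")
def target_small(dgm):
    return simulate_population(PBR_2019_MARGINS, 5000, np.random.SeedSequence((BASE_SEED, 2)), params=dgm, s=0)


@pytest.fixture(scope="session")
def study_large(dgm):
    """Full-scale study population used by the headline reproduction checks."""
    return simulate_population(NINFEA_MARGINS, 100_000, np.random.SeedSequence((BASE_SEED, 3)), params=dgm, s=1)


@pytest.fixture(scope="session")
def target_large(dgm):
    return simulate_population(PBR_2019_MARGINS, 100_000, np.random.SeedSequence((BASE_SEED, 4)), params=dgm, s=0)


@pytest.fixture()
def tiny_table():
    """Four handwritten subjects covering all categorical levels."""
    return pd.DataFrame(
        {
            "age": [30.0, 33.0, 36.0, 28.0],
            "parity": as_parity([0, 1, 2, 0]),
            "education": as_education(["high", "medium", "low", "high"]),
            "a": [1.0, 0.0, 1.0, 0.0],
            "y": [1.0, 0.0, 0.0, 1.0],
        }
    )


def drop_outcomes(pop):
    return pop.drop(columns=[c for c in ("a", "y") if c in pop.columns])
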