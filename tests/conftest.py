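import numpy as np
import pandas as pd
import pytest

from zetacomm import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-shaped dataset: 56 plots, 2 districts, 4 months."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Compact dataset for pipeline round-trips."""
    return generate_dataset(SimulationConfig(
        n_plots=12, n_species=60, n_lost_samples=0, seed=7))


@pytest.fixture
def toy_incidence():
    """4 plots x 4 species with occupancies 3, 2, 2, 1 (hand-checkable)."""
    return pd.DataFrame(
        [[1, 1, 0, 1],
         [1, 1, 1, 0],
         [1, 0, 1, 0],
         [0, 0, 0, 0]],
        index=list("ABCD"), columns=["s1", "s2", "s3", "s4"])


@pytest.fixture
def dieback_categories():
    def make(index):
        n = len(index)
        reps = np.array([18, 15, 23]) * n // 56
        reps[0] += n - reps.sum()
        return pd.Series(np.repeat(["low", "medium", "high"], reps),
                         index=index)
    return make
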