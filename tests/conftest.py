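import warnings

import numpy as np
import pandas as pd
import pytest

from panelforge import SimulationConfig, simulate_abundance

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design used across tests: same group sizes and
    plex structure, fewer proteins."""
    return SimulationConfig(
        n_proteins=200, n_planted=5, effect_log2fc=0.8, noise_sd=0.25, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_abundance(small_config)


@pytest.fixture()
def tiny_matrix():
    """4 proteins x 4 samples with one missing cell."""
    return pd.DataFrame(
        {
            "s1": [0.6, 1.0, 1.1, 0.9],
            "s2": [0.8, np.nan, 1.0, 1.2],
            "s3": [1.0, 0.9, 1.3, 0.7],
            "s4": [1.2, 1.1, 0.8, 5.0],
        },
        index=pd.Index([f"P{i}" for i in range(4)], name="protein"),
    )
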