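import numpy as np
import pandas as pd
import pytest

from thermocal import (
    default_study_config,
    generate_study,
    group_kfold,
    pair_replicates,
)


@pytest.fixture(scope="session")
def default_config():
    return default_study_config(seed=0)


@pytest.fixture(scope="session")
def study_table(default_config):
    """Default synthetic study: 40 participants x 2 rounds x 2 devices x 15."""
    return generate_study(default_config)


@pytest.fixture(scope="session")
def paired(study_table):
    return pair_replicates(study_table)


@pytest.fixture(scope="session")
def folds(paired):
    return group_kfold(paired["participant_id"], k=5, seed=0)


@pytest.fixture
def tiny_table():
    """One participant, one round, both devices, two replicates."""
    return pd.DataFrame(
        {
            "participant_id": ["P1"] * 4,
            "round": ["R1"] * 4,
            "device": ["test", "test", "reference", "reference"],
            "replicate": [1, 2, 1, 2],
            "temperature_c": [34.0, 34.2, 35.0, 35.1],
        }
    )


@pytest.fixture(scope="session")
def linear_xy():
    """Clean monotone calibration problem: y = x + N(0, 0.5)."""
    rng = np.random.default_rng(42)
    x = rng.uniform(30.0, 38.0, 500)
    y = x + rng.normal(0.0, 0.5, 500)
    return x, y
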