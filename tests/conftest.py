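"""Shared fixtures: synthetic training and survey populations.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

import numpy as np
import pandas as pd
import pytest

import dietcorrect as dc


@pytest.fixture(scope="session")
def open_train():
    """Noisy training table (n=2000, noise SD 5) with known true model."""
    return dc.generate_open_like(dc.OpenLikeConfig(n=2000, noise_sd=5.0, seed=1))


@pytest.fixture(scope="session")
def open_train_noiseless():
    """Noise-free training table: misreporting is exactly linear."""
    return dc.generate_open_like(dc.OpenLikeConfig(n=1000, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def nhanes_pop():
    """2007-flavor survey population with ~32% implausible reports."""
    df, strata = dc.generate_nhanes_like(
        dc.NhanesLikeConfig(n=10_000, implausible_fraction_target=0.32, seed=11))
    return df, strata


@pytest.fixture
def tiny_persons():
    """Five hand-written person rows covering both sexes and all age bands."""
    return pd.DataFrame({
        "id": range(5),
        "sex": [1, 2, 1, 2, 1],
        "age_years": [25.0, 40.0, 55.0, 65.0, 70.0],
        "weight_kg": [70.0, 60.0, 85.0, 62.0, 78.0],
        "height_cm": [178.0, 163.0, 180.0, 160.0, 175.0],
        "ei_claimed_kcal": [2500.0, 1800.0, 2200.0, 1500.0, 2000.0],
        "race_group": ["nonblack"] * 5,
    })
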