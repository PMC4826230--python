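import numpy as np
import pandas as pd
import pytest

from mirqval import (
    ControlProfile,
    SimulationConfig,
    curate_matrix,
    generate_study,
)

SMALL_GROUPS = {"NSCLC": 20, "COPD": 10, "control": 8}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced study (38 samples, 40 target assays) for fast unit tests."""
    return SimulationConfig(
        n_per_group=dict(SMALL_GROUPS),
        n_assays=40,
        n_planted=6,
        effect_size=2.5,
        seed=20240917,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_curated(small_study):
    wells, _, _ = small_study
    return curate_matrix(wells)


@pytest.fixture(scope="session")
def small_groups(small_study) -> pd.Series:
    _, annotation, _ = small_study
    return annotation.set_index("sample_id")["group"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def clean_control_config(**overrides) -> SimulationConfig:
    """Config whose single reference control carries only the loading offset,
    so delta-Ct noise equals ``biological_sd`` exactly."""
    base = dict(
        n_per_group={"NSCLC": 74, "COPD": 26, "control": 20},
        n_assays=128,
        control_profiles=(ControlProfile("RNU44", 12.0, 1.0),),
        loading_sd=1.0,
        biological_sd=1.0,
        dropout_base=0.0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
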