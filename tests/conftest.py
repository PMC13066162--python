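"""Shared fixtures: the default synthetic dataset, filtered once per session."""

import numpy as np
import pytest

from pulseflux import (
    GeneratorConfig,
    generate_records,
    ldf_feature_table,
    ppg_feature_table,
)
from pulseflux.pipeline import filter_records

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_records(default_config):
    return generate_records(default_config)


@pytest.fixture(scope="session")
def filtered_records(default_records):
    return filter_records(default_records)


@pytest.fixture(scope="session")
def ppg_table(filtered_records):
    ppg = [r for r in filtered_records if r.modality == "ppg"]
    return ppg_feature_table(ppg)


@pytest.fixture(scope="session")
def ldf_table(filtered_records):
    ldf = [r for r in filtered_records if r.modality == "ldf"]
    return ldf_feature_table(ldf)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
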