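import numpy as np
import pytest

from chunkrecall import ModelParams, compression_config, generate_recall_corpus
from chunkrecall.pipeline import template_designs


@pytest.fixture(scope="session")
def standard_params() -> ModelParams:
    """The model's standard operating point used across the tests."""
    return ModelParams(
        peak=6.0, step=1.0, sigma_select=0.5, sigma_omit=1.0, theta=1.0, decay=0.95
    )


@pytest.fixture(scope="session")
def exp5_designs():
    return template_designs("exp5-triples-6")


@pytest.fixture(scope="session")
def exp6_designs():
    return template_designs("exp6-triples-7")


@pytest.fixture(scope="session")
def small_corpus(exp5_designs):
    """A small simulated corpus (chunk-atomic process) shared across tests."""
    cfg = compression_config(master_seed=42, n_participants=5, trials_per_condition=8)
    return generate_recall_corpus(cfg, exp5_designs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
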