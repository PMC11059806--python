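import numpy as np
import pytest

from retinapop.config import default_config
from retinapop.population import (build_shape_model, generate_individual,
                                  sample_population)


def make_tiny_config(seed: int = 0):
    """Down-scaled configuration for fast end-to-end tests: small trees and
    coarse capillary beds, all other parameters at their defaults."""
    cfg = default_config(seed=seed)
    for st, n in zip(cfg.stages, (48, 24, 12)):
        st.N_terms = n
    for pc, n in zip(cfg.plexi.values(), (400, 700, 500)):
        pc.N_seeds = n
    return cfg


@pytest.fixture(scope="session")
def tiny_config():
    return make_tiny_config()


@pytest.fixture(scope="session")
def shape_model(tiny_config):
    return build_shape_model(tiny_config, np.random.default_rng(5))


@pytest.fixture(scope="session")
def tiny_individual(tiny_config, shape_model):
    """One fully generated and solved tiny virtual eye (shared, read-only)."""
    rng = np.random.default_rng(5)
    params = sample_population(1, rng, tiny_config)[0]
    return generate_individual(params, tiny_config, 11, shape_model=shape_model)
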