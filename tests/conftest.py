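import numpy as np
import pytest
from hypothesis import settings

import conformcl as c

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_encoder():
    """Small encoder for oracle and invariance tests."""
    cfg = c.EncoderConfig(hidden_dim=8, n_layers=2, n_rbf=6, cutoff=5.0, embed_dim=6, n_elements=20)
    return c.SchNetEncoder(cfg, seed=1)


@pytest.fixture(scope="session")
def butane_pool():
    return c.build_pool("CCCC", n_candidates=30, pool_size=5, seed=7)


@pytest.fixture(scope="session")
def fixture_dataset():
    return c.generate_fixture_dataset(40, seed=3)


def random_molecule(rng, n_atoms=None, max_z=16):
    n = n_atoms or int(rng.integers(3, 9))
    return c.Molecule3D(rng.integers(1, max_z, size=n), rng.normal(size=(n, 3)) * 1.5)
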