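import numpy as np
import pytest

from organellekit import SimConfig, generate_organelle_pair


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    config = SimConfig(seed=11)
    mts, cp, truth = generate_organelle_pair(config)
    return config, mts, cp, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
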