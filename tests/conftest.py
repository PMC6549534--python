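import numpy as np
import pytest

from methcascade import synthio


@pytest.fixture(scope="session")
def default_config():
    return synthio.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_data(default_config):
    """One full synthetic cohort at the default study design, seed 1."""
    return synthio.generate_all(default_config)


@pytest.fixture(scope="session")
def small_config():
    """A light cohort for fast structural tests."""
    return synthio.GeneratorConfig(
        n_genes=40, n_drivers=2, n_passengers=3, n_late_dm=3,
        cgi_promoter_fraction=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return synthio.generate_all(small_config)


def random_sequence(rng: np.random.Generator, length: int, p=None) -> str:
    bases = np.array(list("ACGT"))
    return "".join(rng.choice(bases, size=length, p=p))
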