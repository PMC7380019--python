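import numpy as np
import pytest

from rflscan.motif_model import load_packaged_profiles


@pytest.fixture(scope="session")
def profiles():
    return load_packaged_profiles()


@pytest.fixture(scope="session")
def p_profile(profiles):
    return profiles["P"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(np.array(list(AA20))[rng.integers(0, 20, n)])


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
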