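import numpy as np
import pytest

from orbimine.profiles import CANONICAL_RESIDUES, build_canonical_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def canonical_profiles():
    return build_canonical_profiles()


@pytest.fixture(scope="session")
def profile1(request):
    return build_canonical_profiles()[0]


def random_protein(rng, n):
    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=n))


@pytest.fixture
def make_random_protein():
    return random_protein
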