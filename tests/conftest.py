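import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swsearch import GapPenalty, ScoringScheme, load_matrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def blosum50():
    return load_matrix("BLOSUM50")


@pytest.fixture(scope="session")
def scheme62(blosum62):
    """BLOSUM62 with the standard 10-2k gap penalty."""
    return ScoringScheme(blosum62, GapPenalty(10, 2))


@pytest.fixture(scope="session")
def scheme50_textbook(blosum50):
    """BLOSUM50 with open=0, extend=8: the classic worked example."""
    return ScoringScheme(blosum50, GapPenalty(0, 8))


def random_protein_str(rng, length):
    return "".join(rng.choice(AA20, length))


def low_complexity_protein(rng, length):
    """Runs of repeated residues; induces deep vertical-gap propagation."""
    out = []
    while len(out) < length:
        out.extend(rng.choice(AA20) * int(rng.integers(1, 7)))
    return "".join(out[:length])


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
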