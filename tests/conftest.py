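import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(42))


@pytest.fixture(scope="session")
def nt_scheme():
    from matzyg import ScoringScheme

    return ScoringScheme.nucleotide()


@pytest.fixture(scope="session")
def unit_scheme():
    """Match +1 / mismatch -1, gap open 2 extend 1: easy hand arithmetic."""
    from matzyg import ScoringScheme

    return ScoringScheme.nucleotide(match=1, mismatch=-1, gap_open=2, gap_extend=1)


@pytest.fixture(scope="session")
def aa_scheme():
    from matzyg import ScoringScheme

    return ScoringScheme.translated()


@pytest.fixture(scope="session")
def small_pair_set():
    """A 12-family two-species set with one duplication, one loss."""
    from matzyg import generate_transcript_pair_set

    return generate_transcript_pair_set(12, seed=11, n_duplications=1, n_losses=1)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
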