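import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    """A 6 kb random genome with one promoter mid-sequence."""
    from isoscreen.promoters import PromoterRecord

    seq = random_seq(rng, 6000)
    genome = {"chr1": seq}
    promoter = PromoterRecord("G0001_P1", "G0001", "chr1", 3000, "+", "P1")
    return genome, promoter
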