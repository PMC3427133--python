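import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120622)


@pytest.fixture
def random_contig(rng):
    """Factory for random contigs of a given length."""
    from polyptome.seqio import Contig, decode_bases

    def make(length: int, cid: str = "c") -> Contig:
        return Contig(cid, decode_bases(rng.integers(0, 4, length).astype("uint8")))

    return make
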