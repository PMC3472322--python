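import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_reads(rng):
    """100 random equal-length reads with qualities."""
    from radml.io_qc import ReadRecord

    reads = []
    for i in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        quals = rng.integers(2, 41, size=50).tolist()
        reads.append(ReadRecord(id=f"r{i}", sequence=seq, qualities=quals))
    return reads
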