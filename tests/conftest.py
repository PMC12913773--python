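import numpy as np
import pytest
from hypothesis import settings

from apobecsig import synthetic_data as sd
from apobecsig.variant_io import ReferenceContext

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference() -> ReferenceContext:
    """30 kb seeded reference; long enough to host every trinucleotide."""
    return sd.make_reference(length=30_000, gc=0.45, seed=11)


@pytest.fixture(scope="session")
def six_signatures():
    """Six distinguishable synthetic signatures for refit tests."""
    return sd.make_signatures(
        ["sbs2-like", "sbs13-like", "flat", "c-to-a-skewed", "random-1", "random-2"],
        seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
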