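import numpy as np
import pytest
from hypothesis import settings

from gcrsig.chromosome import AssayLayout, build_assay_chromosome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def chrom50():
    """A 50 kb test-scale assay chromosome."""
    return build_assay_chromosome(AssayLayout(length=50_000, seed=3))


@pytest.fixture(scope="session")
def chrom_full():
    """The full-scale (580 kb) assay chromosome."""
    return build_assay_chromosome(AssayLayout(length=580_000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1729)
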