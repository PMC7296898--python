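import pytest

from reanno.core import ThresholdConfig
from reanno.simulate import make_genome


@pytest.fixture(scope="session")
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def truth():
    """The standard 50 kb planted-truth fixture used across modules."""
    return make_genome(seed=1, length_bp=50_000, n_genes=30, n_pseudogenes=5, n_ncrnas=10, gc=0.50)


@pytest.fixture(scope="session")
def small_truth():
    """A cheaper fixture for per-operation tests."""
    return make_genome(seed=7, length_bp=12_000, n_genes=8, n_pseudogenes=3, n_ncrnas=3, gc=0.45)
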