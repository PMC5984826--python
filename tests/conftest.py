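import pytest

from fidpd.fixtures import make_benchmark
from fidpd.model import FunctionalSitePredictor


@pytest.fixture(scope="session")
def benchmark():
    """The default miniature benchmark: 3 families x 8 members, rate 0.15."""
    return make_benchmark(rng_seed=42)


@pytest.fixture(scope="session")
def fitted(benchmark):
    """A predictor fitted on the default benchmark (n-top selection)."""
    est = FunctionalSitePredictor(n_top=6, random_state=1)
    est.fit(benchmark.domains, msas=benchmark.msas)
    return est
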