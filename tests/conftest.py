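import pytest

from orchardssc.config import OrchardConfig, SpectraConfig
from orchardssc.preprocess import second_derivative
from orchardssc.synthetic import generate_orchard, generate_spectra


@pytest.fixture(scope="session")
def spectra_pool():
    """Reference-pool-sized spectra table (800 scans/year x 3 years)."""
    return generate_spectra(SpectraConfig(n_samples=2400, seed=7))


@pytest.fixture(scope="session")
def deriv_pool(spectra_pool):
    return second_derivative(spectra_pool)


@pytest.fixture(scope="session")
def small_orchard():
    """Two seasons, 16 trees, 48 fruit, 8 weekly visits."""
    cfg = OrchardConfig(
        design={2016: (8, 24), 2017: (8, 24)},
        weeks=tuple(range(8, 16)),
        seed=42,
    )
    return generate_orchard(cfg)
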