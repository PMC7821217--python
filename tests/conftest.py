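import numpy as np
import pytest

from pultriage import CoefficientSet, CohortConfig, generate_cohort, inject_missingness


@pytest.fixture(scope="session")
def coefs():
    """Shipped synthetic coefficient sets, keyed by model name."""
    return CoefficientSet.defaults()


@pytest.fixture(scope="session")
def small_cohort():
    """Complete ~800-record cohort over 4 centres (no missingness)."""
    cfg = CohortConfig(n=800, seed=101, centre_fractions=(0.4, 0.3, 0.2, 0.1))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def missing_cohort():
    """~1500-record cohort with default missingness injected."""
    cfg = CohortConfig(n=1500, seed=202, centre_fractions=(0.4, 0.3, 0.2, 0.1))
    cohort, _ = inject_missingness(generate_cohort(cfg), cfg)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
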