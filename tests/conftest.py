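import numpy as np
import pytest

from cyberloop.gene_models import (
    default_gal1_parameters,
    default_irma_parameters,
)


@pytest.fixture(scope="session")
def irma_params():
    """Shipped IRMA parameter set (tau = 100 min)."""
    return default_irma_parameters()


@pytest.fixture(scope="session")
def irma_nodelay(irma_params):
    return irma_params.with_tau(0.0)


@pytest.fixture(scope="session")
def gal1_params():
    return default_gal1_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240515)
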