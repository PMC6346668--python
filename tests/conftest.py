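import numpy as np
import pytest

from cddnet import AsymCopulaSpec, cyclic_var_matrix


@pytest.fixture(scope="session")
def model3_copula() -> AsymCopulaSpec:
    """The asymmetric copula used for the VAR asymmetric-noise model."""
    return AsymCopulaSpec(theta1=5000.0, theta2=5.0, alpha=0.7, beta=0.3)


@pytest.fixture(scope="session")
def var_A() -> np.ndarray:
    """Three-region cyclic VAR(1) coefficient matrix (0.5 couplings)."""
    return cyclic_var_matrix()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
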