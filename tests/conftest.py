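import warnings

import numpy as np
import pytest

from sipsolve import (
    nonlinear_beta_prior,
    nonlinear_uniform_prior,
    make_target_nonlinear,
)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # GMM/MLP convergence chatter is expected at test scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230668)


@pytest.fixture(scope="session")
def nonlinear_target():
    """Truncated-normal target of the nonlinear-system benchmark."""
    return make_target_nonlinear(10000, seed=7)


@pytest.fixture(scope="session")
def uniform_prior():
    return nonlinear_uniform_prior()


@pytest.fixture(scope="session")
def beta_prior():
    return nonlinear_beta_prior()
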