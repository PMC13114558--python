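import numpy as np
import pytest

from ldpcusum import ChangeModel


@pytest.fixture
def gaussian_shift():
    """Unit-variance Gaussian mean shift N(0,1) -> N(1,1)."""
    return ChangeModel.gaussian_mean_1d(0.0, 1.0)


@pytest.fixture
def laplace_shift():
    """Unit-scale Laplace location shift Lap(0,1) -> Lap(0.5,1)."""
    return ChangeModel.laplace_mean_1d(0.0, 0.5)


@pytest.fixture
def variance_shift():
    """Gaussian variance inflation N(0,1) -> N(0,4)."""
    return ChangeModel.gaussian_var_1d(1.0, 4.0)


@pytest.fixture
def mean_shift_5d():
    """5-d Gaussian mean shift N(0, I) -> N(0.5*1, I)."""
    return ChangeModel.gaussian_mean_kd(np.zeros(5), 0.5 * np.ones(5))


@pytest.fixture
def cov_spike_5d():
    """5-d rank-one spiked covariance N(0, I) -> N(0, I + 0.8 uu^T)."""
    u = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
    return ChangeModel.gaussian_cov_spike_kd(u, 0.8)


NAMED_FIXTURES = [
    "gaussian_shift",
    "laplace_shift",
    "variance_shift",
    "mean_shift_5d",
    "cov_spike_5d",
]


@pytest.fixture(params=NAMED_FIXTURES)
def named_model(request):
    """Each of the five study change models in turn."""
    return request.getfixturevalue(request.param)
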