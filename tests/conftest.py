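import numpy as np
import pytest

from bpgrowth.data import walleye_table1
from bpgrowth.fitting import BertalanffyPutter
from bpgrowth.growth import ExponentPair, GrowthParameters

# optimal parameters of the three reference fits on the Walleye table
BERTALANFFY = (ExponentPair(2.0 / 3.0, 1.0), GrowthParameters(203.8, 11.2, 0.86))
LOGISTIC = (ExponentPair(1.0, 2.0), GrowthParameters(301.716, 0.528051, 0.000253611))
GOMPERTZ_OPT = (
    ExponentPair(0.686028, 0.686028),
    GrowthParameters(175.67, 21.3148, 2.76054),
)


@pytest.fixture(scope="session")
def walleye():
    return walleye_table1()


@pytest.fixture(scope="session")
def model(walleye):
    return BertalanffyPutter(walleye)


@pytest.fixture(scope="session")
def fit_bertalanffy(model):
    """Constrained least-squares fit at the classical mass pair (2/3, 1)."""
    return model.fit(ExponentPair(2.0 / 3.0, 1.0), method="constrained-gradient")


@pytest.fixture(scope="session")
def fit_logistic(model):
    return model.fit(ExponentPair(1.0, 2.0), method="constrained-gradient")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
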