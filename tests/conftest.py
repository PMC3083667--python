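import numpy as np
import pytest

from tiedsim import ClimateVariable, MonthlySeries
from tiedsim.climate import FLUX_VARIABLES


def make_series(start_year, end_year, fn=None, constant=None):
    """Build a MonthlySeries from fn(var, year, month) or a constant.

    Flux variables (precipitation, runoff) are clipped at zero to satisfy the
    container invariant; tests asserting on exact values use temperature.
    """
    n = end_year - start_year + 1
    data = {}
    for var in ClimateVariable:
        arr = np.empty((n, 12))
        for k, year in enumerate(range(start_year, end_year + 1)):
            for m in range(1, 13):
                if fn is not None:
                    arr[k, m - 1] = fn(var, year, m)
                else:
                    arr[k, m - 1] = constant
        if var in FLUX_VARIABLES:
            arr = np.clip(arr, 0.0, None)
        data[var] = arr
    return MonthlySeries(start_year, end_year, data)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def constant_series():
    return make_series(2000, 2010, constant=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
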