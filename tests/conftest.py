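import numpy as np
import pandas as pd
import pytest

from pbwphen import ThresholdPair


@pytest.fixture
def thresholds():
    """Field-calibrated pink bollworm thresholds."""
    return ThresholdPair(13.0, 34.0)


def sine_dd_quadrature(tmin, tmax, ltt, utt, n=40001):
    """Independent oracle: trapezoid quadrature of the clamped sine over one period."""
    m = (tmin + tmax) / 2.0
    a = (tmax - tmin) / 2.0
    theta = np.linspace(-np.pi / 2, 3 * np.pi / 2, n)
    y = np.clip(np.minimum(m + a * np.sin(theta), utt) - ltt, 0.0, None)
    return float(np.trapezoid(y, theta) / (2 * np.pi))


@pytest.fixture
def quadrature_oracle():
    return sine_dd_quadrature


def constant_weather(start, n_days, tmin, tmax):
    """Daily weather with identical tmin/tmax every day."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "tmin": float(tmin), "tmax": float(tmax)})


@pytest.fixture
def flat_weather():
    """One year at 18/28 degC: exactly 10 DD/day between 13 and 34 degC."""
    return constant_weather("2020-01-01", 366, 18.0, 28.0)
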