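import datetime as dt
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

import episurg as ep
from scipy.special import expit


@pytest.fixture
def single_wave_incidence():
    """Noise-free single Gaussian wave, smoothed: one clean peak mid-series."""
    spec = ep.EpidemicCurveSpec(
        waves=[ep.Wave(100, 10, 1000)], n_days=200, start_date=dt.date(2020, 3, 1)
    )
    cum = ep.generate_epidemic_curve(spec)
    return ep.butterworth_smooth(ep.differentiate(cum))


@pytest.fixture
def two_wave_incidence():
    """Two well-separated waves above both detection thresholds."""
    spec = ep.EpidemicCurveSpec(
        waves=[ep.Wave(75, 30, 900), ep.Wave(185, 30, 700)],
        n_days=270,
        start_date=dt.date(2020, 4, 1),
        noise="poisson",
        seed=1,
    )
    cum = ep.generate_epidemic_curve(spec)
    return ep.butterworth_smooth(ep.differentiate(cum))


def draw_ordinal(rng, X, beta, cutpoints):
    """Sample ordinal outcomes from the cumulative-logit model."""
    n = len(X)
    eta = X @ beta if len(beta) else np.zeros(n)
    cut = np.asarray(cutpoints, float)
    cum = expit(cut[None, :] - eta[:, None])
    probs = np.diff(np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))]), axis=1)
    return (rng.random(n)[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
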