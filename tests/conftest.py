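import warnings

import numpy as np
import pandas as pd
import pytest

import cgmchaos as cc

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def henon_series():
    return cc.generate_chaotic_benchmark("henon", n=5000, seed=1)


@pytest.fixture(scope="session")
def logistic_series():
    return cc.generate_chaotic_benchmark("logistic", n=5000, seed=2)


@pytest.fixture(scope="session")
def cgm_day():
    """One day of moderately variable synthetic CGM."""
    cfg = cc.SimulationConfig(
        days=1, seed=2, noise_sd=5.0, hypo_intensity=0.2, hyper_intensity=0.2
    )
    return cc.simulate_cgm(cfg)


@pytest.fixture
def series_from_values():
    def make(values, start="2024-01-01 00:00:00", interval=5.0):
        ts = pd.date_range(start, periods=len(values), freq=f"{int(interval)}min")
        return cc.GlucoseSeries(ts, np.asarray(values, float), interval)

    return make
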