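import warnings

import numpy as np
import pandas as pd
import pytest

from nof1ema import synth

# statsmodels ARIMA emits frequency/convergence chatter on short series
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def complete_participant():
    """One fully observed synthetic participant (no missingness)."""
    cfg = synth.SimulationConfig(missing_rate=0.0, seed=101)
    return synth.simulate_participant(cfg)


@pytest.fixture(scope="session")
def likert_ema_with_missing():
    """EMA table with ~15% record-level missingness for imputation tests."""
    cfg = synth.SimulationConfig(missing_rate=0.15, seed=202)
    return synth.simulate_participant(cfg).ema


def poisson_series(n, beta, seed, mean_count=11.7, ar=0.5,
                   predictor_mean=3.18, predictor_sd=0.93, dow_amp=0.0):
    """Log-link Poisson counts driven by an AR(1) Gaussian predictor."""
    rng = np.random.default_rng(seed)
    spec = synth.PredictorSpec("usefulness", predictor_mean, predictor_sd,
                               ar, kind="continuous")
    x = synth.generate_predictor_series(spec, n, rng)
    dow = (np.arange(n) // 2) % 7
    eta = (np.log(mean_count) + beta * (x - predictor_mean)
           + dow_amp * np.sin(2 * np.pi * dow / 7))
    y = rng.poisson(np.exp(eta)).astype(float)
    return pd.DataFrame({"usefulness": x, "frequency": y,
                         "dow": dow.astype(float)})
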