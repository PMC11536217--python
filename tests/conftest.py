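import numpy as np
import pytest

from idmproj.projection_engine import build_synthetic_study
from idmproj.synthetic_data import SynthConfig, gen_consistent_history, gen_covid_series
from idmproj.wave_model import fit_waves


@pytest.fixture(scope="session")
def config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def history_female(config):
    return gen_consistent_history(config, "female")


@pytest.fixture(scope="session")
def covid_series(config):
    return gen_covid_series(config)


@pytest.fixture(scope="session")
def covid_series_noiseless(config):
    cfg = SynthConfig(seed=config.seed, noise_sd=0.0)
    return gen_covid_series(cfg)


@pytest.fixture(scope="session")
def study(config):
    """(inputs, ground-truth waves, weekly series) for the default config."""
    return build_synthetic_study(config)


@pytest.fixture(scope="session")
def fitted_waves(covid_series):
    series, _ = covid_series
    return fit_waves(series["time"], series["rate"], k=7)
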