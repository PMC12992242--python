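import pandas as pd
import pytest

from cndc.synthetic import SyntheticTrialConfig, generate_trial
from cndc.trial_data import block_level_samples, observations_to_frame, yields_to_frame


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SyntheticTrialConfig(noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_cfg):
    return generate_trial(noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    cfg = SyntheticTrialConfig(noise_cv=0.05, seed=7)
    return cfg, generate_trial(cfg)


@pytest.fixture
def trial_csv(tmp_path, noisy_trial):
    """One noisy year written in the canonical CSV schema."""
    _, (obs, yields, _) = noisy_trial
    tpath = tmp_path / "trial.csv"
    ypath = tmp_path / "yields.csv"
    observations_to_frame(obs).drop(columns="n_uptake_kg_ha").to_csv(tpath, index=False)
    yields_to_frame(yields).to_csv(ypath, index=False)
    return tpath, ypath


@pytest.fixture(scope="session")
def whole_plant_plots(noisy_trial):
    _, (obs, _, _) = noisy_trial
    return block_level_samples(obs, part="whole_plant")
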