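import numpy as np
import pytest

from dyadeeg.durations import DurationModel
from dyadeeg.simulate import DyadEEGConfig, ErpTemplate, GameConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_short_game_config():
    """A 30-s game with fast kills and frequent deaths, so small datasets
    contain every event class."""
    return GameConfig(
        game_length_s=30.0,
        start_to_kill=DurationModel.gamma_from_mean(240.0, shape=3.0, shift=90.0),
        kill_to_kill=DurationModel.gamma_from_mean(300.0, shape=3.0, shift=120.0),
        death_rate_per_game=2.0,
        death_models={
            "ShooterDeath": (
                DurationModel.gamma_from_mean(120.0, shape=2.0, shift=40.0),
                DurationModel.gamma_from_mean(120.0, shape=2.0, shift=40.0),
            ),
            "BaitDeath": (
                DurationModel.gamma_from_mean(120.0, shape=2.0, shift=40.0),
                DurationModel.gamma_from_mean(120.0, shape=2.0, shift=40.0),
            ),
        },
    )


def make_quiet_eeg_config():
    """Few electrodes, strong templates, no jitter: fast and high-SNR."""
    return DyadEEGConfig(
        electrodes=("FZ", "CZ", "PZ", "O1", "O2"),
        noise_sd=3.0,
        templates={
            ("Shooter", "Kill"): ErpTemplate(6.0, 0.28),
            ("Shooter", "ShooterDeath"): ErpTemplate(10.0, 0.33),
            ("Shooter", "BaitDeath"): ErpTemplate(6.0, 0.40),
            ("Bait", "Kill"): ErpTemplate(4.0, 0.32),
            ("Bait", "ShooterDeath"): ErpTemplate(7.0, 0.38),
            ("Bait", "BaitDeath"): ErpTemplate(11.0, 0.35),
        },
        latency_jitter_sd_s=0.0,
    )


@pytest.fixture
def short_game_config():
    return make_short_game_config()


@pytest.fixture
def quiet_eeg_config():
    return make_quiet_eeg_config()
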