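import numpy as np
import pytest

from ictalock.gswd import detect_gswds
from ictalock.synth import SynthConfig, generate_ecog, generate_purkinje_train


@pytest.fixture(scope="session")
def modulated_bundle():
    """One synthetic recording with strongly phase-locked SS and CS firing."""
    cfg = SynthConfig(
        total_duration=130.0,
        n_episodes=20,
        gswd_rate_mean=7.0,
        gswd_rate_sd=0.0,
        mod_depth_ss=0.8,
        mod_depth_cs=0.8,
        phase_ss_deg=90.0,
        phase_cs_deg=90.0,
        seed=3,
    )
    rec, truth = generate_ecog(cfg)
    episodes = detect_gswds(rec)
    train = generate_purkinje_train(cfg, truth, unit_id="PC0")
    return cfg, rec, truth, episodes, train


@pytest.fixture(scope="session")
def quiet_bundle():
    """A recording with episodes but an unmodulated Purkinje cell."""
    cfg = SynthConfig(total_duration=130.0, n_episodes=20, seed=4)
    rec, truth = generate_ecog(cfg)
    episodes = detect_gswds(rec)
    train = generate_purkinje_train(cfg, truth, unit_id="PC0")
    return cfg, rec, truth, episodes, train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
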