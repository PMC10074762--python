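import numpy as np
import pytest

import revpitch as rp


@pytest.fixture(scope="session")
def speech_cfg():
    return rp.speech_config()


@pytest.fixture(scope="session")
def tone_cfg():
    return rp.complex_tone_config()


@pytest.fixture(scope="session")
def melody_cfg():
    return rp.melody_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simulate_one(config, template, internal_noise_ratio=0.0, lapse_rate=0.0,
                 seed=0, n_trials=None, group="g", pid="p1"):
    """Build pool, pair and simulate one session; shared test helper."""
    import dataclasses

    if n_trials is not None and n_trials != config.n_trials:
        config = dataclasses.replace(config, n_trials=n_trials,
                                     pool_size=2 * n_trials)
    gen = np.random.default_rng(seed)
    pool = rp.build_stimulus_pool(config, gen)
    pairs = rp.pair_trials(pool, gen)
    obs = rp.ObserverSpec(pid, group, template,
                          internal_noise_ratio=internal_noise_ratio,
                          lapse_rate=lapse_rate, seed=seed)
    return rp.simulate_session(obs, pairs, config, rng=gen), obs


@pytest.fixture(scope="session")
def noisy_speech_session(speech_cfg):
    """One realistic speech session (cubic template, moderate noise)."""
    session, obs = simulate_one(speech_cfg, rp.make_template("cubic", 8),
                                internal_noise_ratio=2.0, seed=77)
    return session, obs
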