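import warnings

import numpy as np
import pytest

from cbgtclaw import claw, synth


@pytest.fixture(scope="session")
def default_cfg():
    return synth.default_config()


@pytest.fixture(scope="session")
def pre_trials(default_cfg):
    """Decided pre-learning trials pooled over a few jittered networks."""
    trials = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for net in range(4):
            cfg = synth.sample_network(default_cfg, 0.05, seed=net)
            rng = np.random.default_rng(300 + net)
            for _ in range(50):
                r = synth.simulate_trial(cfg, None, rng)
                if r.decided:
                    trials.append(r)
    return trials


@pytest.fixture(scope="session")
def claw_model(pre_trials):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return claw.ClawModel().fit(pre_trials)
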