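import numpy as np
import pytest

from somnis import synth


@pytest.fixture(scope="session")
def iso_session():
    """One standard ISO anesthesia session with ground truth (shared)."""
    cfg = synth.anesthesia_config("ISO", seed=11, n_neurons=20)
    session, truth = synth.make_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def sleep_session():
    """One standard sleep-wake session with ground truth (shared)."""
    cfg = synth.sleep_config(seed=12, n_neurons=20, total_s=2400.0)
    session, truth = synth.make_session(cfg)
    return cfg, session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
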