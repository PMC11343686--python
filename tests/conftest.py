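import logging

import numpy as np
import pytest

import grcbasis as g
from grcbasis.pipeline import analyze_session

logging.getLogger("grcbasis").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_expert():
    """A compact expert session plus its full analysis report."""
    cfg = g.SynthConfig(n_grc=60, n_cf=12, n_trials=60,
                        frac_anticipatory=0.4, seed=7)
    session = g.simulate_session(cfg)
    report = analyze_session(session)
    return session, report


@pytest.fixture(scope="session")
def big_expert():
    """The reference expert session: 150 GrCs, 40% anticipatory ramps with
    centers spread over the 1.1-s delay, noise sigma 1, 100 trials."""
    cfg = g.SynthConfig(n_grc=150, n_cf=20, n_trials=100,
                        frac_anticipatory=0.4, seed=0)
    session = g.simulate_session(cfg)
    report = analyze_session(session)
    return session, report


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Deterministic-limit config: no noise, drift, bleach, or background."""
    return dict(noise_sigma=0.0, bleach_amps=(0.0, 0.0), drift_amp_frac=0.0,
                baseline_f=0.0, gain=1.0, grc_background_hz=0.0)
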