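"""Shared fixtures: fast simulator configurations and a reusable session.

Unit tests run on reduced sessions (500 Hz, short fixations) so the
whole suite stays quick; nothing in the statistical contracts depends on
the sampling rate or fixation length.
"""

import numpy as np
import pytest

from herpipe import SimConfig, simulate_session
from herpipe.pipeline import detect_peaks


def fast_config(**kw) -> SimConfig:
    defaults = dict(
        n_trials=40,
        fixation_range=(8.0, 12.0),
        sample_rate=500.0,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def coupled_session():
    """One simulated session with strong negative coupling, plus detected peaks."""
    from herpipe import beta_for_implied_r

    cfg = fast_config(seed=7)
    cfg = SimConfig(
        **{
            **cfg.__dict__,
            "coupling_beta": beta_for_implied_r(-0.5, cfg),
        }
    )
    rec, trials, truth = simulate_session(cfg)
    peaks = detect_peaks(rec)
    return {"cfg": cfg, "rec": rec, "trials": trials, "truth": truth, "peaks": peaks}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
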