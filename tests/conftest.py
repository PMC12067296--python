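import numpy as np
import pytest

from remoterep.decoding import (
    decode_session,
    fit_encoding_model,
    running_average_posterior,
)
from remoterep.synthetic import SyntheticSessionConfig, synthesize_session
from remoterep.track import build_track


@pytest.fixture(scope="session")
def geometry():
    return build_track()


@pytest.fixture(scope="session")
def small_session():
    """A compact but complete session shared across the unit tests: default
    track, 60 cells, 8 tetrodes, shortened phases, mixed injected events."""
    cfg = SyntheticSessionConfig(
        seed=42,
        exploration_minutes=5.0,
        feedback_minutes=8.0,
        event_mix={
            "jump": 12,
            "jump_arm_base": 3,
            "medium_trajectory": 2,
            "long_trajectory": 2,
        },
        n_swr=15,
    )
    return synthesize_session(cfg)


@pytest.fixture(scope="session")
def small_decode(small_session):
    s = small_session
    model = fit_encoding_model(s.spikes, s.trace, s.geometry, s.exploration_end)
    decoded_expl = decode_session(s.spikes, model, s.geometry, 0.0, s.exploration_end)
    decoded_fb = decode_session(
        s.spikes, model, s.geometry, s.exploration_end, s.feedback_end
    )
    averaged = running_average_posterior(decoded_fb)
    return model, decoded_expl, decoded_fb, averaged


def match_event(det_time, gt_events, slack=0.05):
    """Ground-truth event whose window contains a detection time, or None."""
    for g in gt_events:
        if g.time <= det_time <= g.time + g.duration + slack:
            return g
    return None


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
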