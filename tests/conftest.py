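"""Shared fixtures: small synthetic sessions built at test time.

Desk-scale sessions use a shortened mean inter-trial interval (the design
exposes it) so a full 32-trial session spans ~20 min of simulated time
instead of ~2 h; trial composition, cue timing and shock scheduling are
unchanged.
"""

import numpy as np
import pytest

from vlpag import suppression, synth
from vlpag.session import Session, default_design


SHORT_ITI = dict(mean_iti=40.0)
MIN_ITI = 15.0


@pytest.fixture(scope="session")
def design():
    return default_design(**SHORT_ITI)


@pytest.fixture(scope="session")
def trials(design):
    return synth.make_trial_sequence(design, seed=11, min_iti=MIN_ITI)


@pytest.fixture(scope="session")
def behavior_session(design, trials):
    """Session with behavior only (no units)."""
    span = synth.session_span_for(trials, design)
    beh = synth.simulate_pokes(trials, synth.BehaviorSpec(), seed=12,
                               design=design, session_span=span)
    return Session(design=design, trials=trials, behavior=beh, units=[],
                   session_span=span, session_id="beh-only")


@pytest.fixture(scope="session")
def measures(behavior_session):
    return suppression.compute_suppression(behavior_session)


@pytest.fixture(scope="session")
def mixed_session(design):
    """One session with a few units of every profile (ground truth known)."""
    specs = (
        [synth.DEFAULT_PROFILES["onset"]] * 3
        + [synth.DEFAULT_PROFILES["ramping"]] * 3
        + [synth.DEFAULT_PROFILES["hfr"]] * 2
        + [synth.DEFAULT_PROFILES["nonresponsive"]] * 4
    )
    session = synth.simulate_session(design, synth.BehaviorSpec(), specs,
                                     seed=21, min_iti=MIN_ITI)
    truth = ["onset"] * 3 + ["ramping"] * 3 + ["hfr"] * 2 + ["nonresponsive"] * 4
    return session, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
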