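import logging

import numpy as np
import pytest

from callscale import ActivityMask, CallEvent, DyadRecording

logging.getLogger("callscale").setLevel(logging.ERROR)


@pytest.fixture
def roles():
    return {"F": "female", "M": "male"}


@pytest.fixture
def four_event_recording(roles):
    """F@1.0, F@3.5, M@4.0, F@9.0 under an all-covering window."""
    events = [
        CallEvent("F", 1.0),
        CallEvent("F", 3.5),
        CallEvent("M", 4.0),
        CallEvent("F", 9.0),
    ]
    return DyadRecording(
        pair_id="p1", roles=roles, events=events, mask=ActivityMask.covering(100.0)
    )


def random_recording(rng: np.random.Generator, n_events: int, roles) -> DyadRecording:
    """A random small dyadic stream with occasional exact ties."""
    times = np.round(np.sort(rng.uniform(0, 50, n_events)), 1)  # ties likely
    individuals = rng.choice(["F", "M"], n_events)
    if len(set(individuals)) < 2:
        individuals[0], individuals[1] = "F", "M"
    events = [CallEvent(str(i), float(t)) for i, t in zip(individuals, times)]
    return DyadRecording(
        pair_id="rnd", roles=dict(roles), events=events, mask=ActivityMask.covering(60.0)
    )
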