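import numpy as np
import pytest

import somnokit as sk


@pytest.fixture(scope="session")
def default_night():
    """One simulated night at default parameters, seed 1."""
    return sk.simulate_night(sk.SimulationParams(), seed=1)


@pytest.fixture(scope="session")
def night_products(default_night):
    """Full detection chain on the default night."""
    session, truth = default_night
    segments, changes = sk.posture_segments(session.pressure)
    toss = sk.detect_toss_turn(session.pressure, segments=segments)
    snore = sk.detect_snore_events(session.sound_db)
    features = sk.epoch_features(session, toss, snore, segments, changes)
    return {"session": session, "truth": truth, "segments": segments,
            "changes": changes, "toss": toss, "snore": snore,
            "features": features}


@pytest.fixture
def tiny_session():
    """A 10 s fully-populated session with benign values."""
    n = 10
    rng = np.random.default_rng(7)
    return sk.SessionRecord(
        pressure=rng.uniform(0, 50, size=(n, 8)),
        sound_db=np.full(n, 25.0),
        body_temp=np.full(n, 36.5),
        room_temp=np.full(n, 22.5),
        humidity=np.full(n, 45.0),
        co2=np.full(n, 500.0),
        lux=np.full(n, 10.0),
        heart_rate=np.full(n, 70.0),
    )
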