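import numpy as np
import pandas as pd
import pytest

from alpgraze.sim.landscape import LandscapeConfig, generate_landscape, generate_rotation
from alpgraze.sim.tracks import inject_gaps, simulate_tracks


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(LandscapeConfig(nrows=32, ncols=32, n_paddocks=3), seed=3)


@pytest.fixture(scope="session")
def rotation(landscape):
    return generate_rotation(landscape, herd_lu=50.0, period_days=2.0, seed=1)


@pytest.fixture(scope="session")
def tracks(landscape, rotation):
    """Three animals, three hours, labelled fixes, no gaps."""
    ts, truth = simulate_tracks(landscape, rotation, n_animals=3, duration=pd.Timedelta(hours=3), seed=5)
    return ts, truth


@pytest.fixture(scope="session")
def gappy_tracks(tracks):
    ts, _ = tracks
    return inject_gaps(ts, fail_rate_per_h=1.0, recover_rate_per_h=4.0, seed=2)


@pytest.fixture(scope="session")
def classification_run():
    """One shared run of the default classification study (seed 1)."""
    from alpgraze.studies import classification_study

    return classification_study(seed=1)


def make_trackset(x, y, t=None, state="grazing", g_t=1, interval=20.0, animal="a"):
    """Small hand-built TrackSet for unit tests."""
    from alpgraze.sim.tracks import TrackSet

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if t is None:
        t = pd.date_range("2011-06-15", periods=n, freq=f"{int(interval)}s")
    state = np.broadcast_to(np.asarray(state, dtype=object), (n,))
    g = np.broadcast_to(np.asarray(g_t), (n,))
    fixes = pd.DataFrame(
        {
            "animal_id": animal,
            "device_id": f"dev-{animal}",
            "t": t,
            "x": x,
            "y": y,
            "state": state,
            "g_t": g,
        }
    )
    return TrackSet(fixes=fixes, devices=[f"dev-{animal}"], nominal_interval=interval)
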