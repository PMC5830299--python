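import numpy as np
import pandas as pd
import pytest

from trackrsf import synthetic
from trackrsf.covariates import CovariateSampler
from trackrsf.tracks import Track


@pytest.fixture(scope="session")
def small_env():
    """Coarse synthetic environment shared across tests (read-only)."""
    return synthetic.make_environment(synthetic.EnvConfig(cell_deg=0.2, n_days=40))


@pytest.fixture(scope="session")
def small_sampler(small_env):
    return CovariateSampler(small_env)


@pytest.fixture(scope="session")
def sea_env():
    """All-sea environment (no land mask) for land-free movement tests."""
    return synthetic.make_environment(
        synthetic.EnvConfig(cell_deg=0.2, n_days=40, coast_lon=None)
    )


def make_track(lats, lons=None, start="2005-11-02T00:00", gap_hours=6.0, animal_id="t0", sex="F", lqs=None):
    """Small helper: build a Track from latitude (and optional longitude) lists."""
    n = len(lats)
    lons = lons if lons is not None else [-170.0] * n
    ts = pd.date_range(start, periods=n, freq=pd.Timedelta(hours=gap_hours))
    data = pd.DataFrame({"timestamp": ts, "lon": lons, "lat": lats})
    if lqs is not None:
        data["lq"] = lqs
    return Track(animal_id=animal_id, sex=sex, data=data)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture(scope="session")
def demo_tracks(small_env, small_sampler):
    """A couple of selective tracks over the shared environment."""
    truth = synthetic.TruthRSF({"sqrt_d2ice": -0.3})
    return synthetic.make_selective_tracks(
        small_env,
        truth,
        synthetic.MovementParams(),
        n_animals=3,
        seed=11,
        n_steps=60,
        sampler=small_sampler,
    )


@pytest.fixture
def rng():
    # function-scoped: every test sees the same deterministic stream,
    # independent of execution order
    return np.random.default_rng(1234)
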