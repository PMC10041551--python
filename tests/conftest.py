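from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from foxmove import Fix, ResidentParams, SimWorld, Track, simulate_resident


@pytest.fixture(scope="session")
def grid_5x5():
    """25-point unit grid, a workhorse for hull oracles."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    return np.column_stack([xs.ravel(), ys.ravel()])


@pytest.fixture(scope="session")
def world():
    return SimWorld()


@pytest.fixture(scope="session")
def resident_track(world):
    """Quiet OU resident: 180 summer-start days, no excursions."""
    params = ResidentParams(excursion_rate=0.0, commuting_rate=0.0)
    track, events = simulate_resident(
        world, params, start_date=date(2019, 5, 20), n_days=180, seed=11
    )
    assert events == []
    return track


def make_track(positions, start=datetime(2020, 1, 1, 12, tzinfo=timezone.utc),
               animal_id="A1", species="red", habitats=None, step_days=1.0):
    """Build a daily track from an (n, 2) position array."""
    positions = np.asarray(positions, dtype=float)
    habitats = habitats or ["land"] * len(positions)
    fixes = [
        Fix(animal_id=animal_id, species=species,
            timestamp=start + timedelta(days=i * step_days),
            x=float(p[0]), y=float(p[1]), habitat=habitats[i])
        for i, p in enumerate(positions)
    ]
    return Track(animal_id=animal_id, species=species, fixes=fixes, thinned=True)
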