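"""Shared synthetic-session fixtures.

Session-scoped so the expensive behaviour simulations are generated once and
reused across metric tests; all seeds are fixed for reproducibility.
"""

import numpy as np
import pytest

from gridspeed import preprocess, simulate as sim, tuning


@pytest.fixture(scope="session")
def of_traj():
    """10-minute open-field trajectory, 8 cm/s mean-speed target."""
    return sim.simulate_trajectory(
        sim.open_field(), sim.TrajectoryParams(duration=600.0, seed=11))


@pytest.fixture(scope="session")
def long_traj():
    """20-minute open-field trajectory for mean-speed / recovery checks."""
    return sim.simulate_trajectory(
        sim.open_field(), sim.TrajectoryParams(duration=1200.0, seed=12))


@pytest.fixture(scope="session")
def speeds40(of_traj):
    return preprocess.compute_speed(of_traj, 0.04)


@pytest.fixture(scope="session")
def speeds500(of_traj):
    return preprocess.compute_speed(of_traj, 0.5)


@pytest.fixture(scope="session")
def binning(of_traj):
    return tuning.SpatialBinning(of_traj, extent=(80.0, 80.0))


@pytest.fixture(scope="session")
def speed_ctx(speeds40):
    return tuning.SpeedScoringContext(speeds40)


@pytest.fixture(scope="session")
def grid_model():
    return sim.UnitModel(kind="grid", base_rate=15.0, grid_spacing=30.0,
                         grid_orientation=10.0, grid_phase=(5.0, 5.0))


@pytest.fixture(scope="session")
def grid_train(of_traj, grid_model):
    return sim.simulate_spikes(sim.unit_rate_function(grid_model), of_traj,
                               seed=21, unit_id="grid0")


@pytest.fixture(scope="session")
def hd_train(of_traj):
    model = sim.UnitModel(kind="hd", base_rate=10.0, hd_mu=90.0, hd_kappa=2.0)
    return sim.simulate_spikes(sim.unit_rate_function(model), of_traj,
                               seed=22, unit_id="hd0")


@pytest.fixture(scope="session")
def speed_train(of_traj):
    model = sim.UnitModel(kind="speed", base_rate=2.0, speed_slope=0.5)
    return sim.simulate_spikes(sim.unit_rate_function(model), of_traj,
                               seed=23, unit_id="speed0")


@pytest.fixture(scope="session")
def untuned_train(of_traj):
    model = sim.UnitModel(kind="untuned", base_rate=5.0)
    return sim.simulate_spikes(sim.unit_rate_function(model), of_traj,
                               seed=24, unit_id="untuned0")


def poisson_train(rate_hz, duration, seed, depth=0.0, freq=8.0, unit_id="u"):
    """Homogeneous or sinusoidally rate-modulated Poisson train (thinning)."""
    from gridspeed.core import SpikeTrain

    rng = np.random.default_rng(seed)
    rmax = rate_hz * (1.0 + depth)
    if rmax == 0:
        return SpikeTrain(unit_id, np.empty(0), duration)
    n = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    accept = rng.uniform(0.0, 1.0, n) < (
        rate_hz * (1.0 + depth * np.cos(2 * np.pi * freq * cand)) / rmax)
    return SpikeTrain(unit_id, cand[accept], duration)
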