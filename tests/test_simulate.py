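"""Generator correctness: trajectory statistics, rate models, Poisson
thinning, and LFP speed-coupling ground truth."""

import numpy as np
import pytest
from scipy import ndimage, stats

from gridspeed import preprocess, simulate as sim, tuning
from gridspeed.core import LFPSignal


class TestTrajectory:
    def test_mean_speed_hits_target(self, long_traj):
        spd = preprocess.compute_speed(long_traj, 0.5)
        assert abs(spd.speed.mean() - 8.0) < 1.0

    def test_sample_count_and_bounds(self):
        traj = sim.simulate_trajectory(
            sim.open_field(), sim.TrajectoryParams(duration=10.0, seed=1))
        assert traj.timestamps.size == 250
        assert np.all((traj.x >= 0) & (traj.x <= 80))
        assert np.all((traj.y >= 0) & (traj.y <= 80))

    def test_deterministic_under_seed(self):
        p = sim.TrajectoryParams(duration=30.0, seed=5)
        a = sim.simulate_trajectory(sim.open_field(), p)
        b = sim.simulate_trajectory(sim.open_field(), p)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.hd_deg, b.hd_deg)

    def test_linear_track_stays_on_track(self):
        traj = sim.simulate_trajectory(
            sim.linear_track(), sim.TrajectoryParams(duration=60.0, seed=2))
        assert np.all((traj.x >= 0) & (traj.x <= 150))

    @pytest.mark.parametrize("bad", [
        dict(duration=-1.0), dict(sample_rate=0.0),
        dict(mean_speed_target=60.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.TrajectoryParams(**bad)

    def test_speed_distribution_spans_analysis_range(self, long_traj):
        spd = preprocess.compute_speed(long_traj, 0.5)
        # scoring assumes coverage of 1-30 cm/s; immobility must exist too
        assert (spd.speed < 1.0).sum() >= 5
        assert spd.speed.max() > 20.0


class TestRateFunctions:
    def test_untuned_rate_constant(self):
        rf = sim.unit_rate_function(sim.UnitModel(kind="untuned", base_rate=5))
        r = rf(np.array([1.0, 40.0]), np.array([2.0, 70.0]),
               np.array([0.0, 180.0]), np.array([0.0, 20.0]),
               np.array([0.0, 100.0]))
        assert np.allclose(r, 5.0)

    def test_grid_lattice_periodicity(self):
        model = sim.UnitModel(kind="grid", base_rate=10.0, grid_spacing=30.0,
                              grid_orientation=0.0, grid_phase=(3.0, 4.0))
        rf = sim.unit_rate_function(model)
        # lattice axes of the three-grating construction are perpendicular
        # to the wave vectors (30 deg, 90 deg, 150 deg); step along 90 deg
        ax = np.radians(90.0)
        x0, y0 = 11.0, 17.0
        x1 = x0 + 30.0 * np.cos(ax)
        y1 = y0 + 30.0 * np.sin(ax)
        r0 = rf(x0, y0, 0.0, 5.0, 0.0)
        r1 = rf(x1, y1, 0.0, 5.0, 0.0)
        assert np.isclose(r0, r1, atol=1e-9)

    def test_grid_peak_equals_base_rate(self):
        model = sim.UnitModel(kind="grid", base_rate=12.0, grid_spacing=30.0,
                              grid_phase=(6.0, 9.0))
        rf = sim.unit_rate_function(model)
        assert np.isclose(rf(6.0, 9.0, 0.0, 0.0, 0.0), 12.0)

    def test_hd_kappa_zero_is_uniform(self):
        rf = sim.unit_rate_function(
            sim.UnitModel(kind="hd", base_rate=7.0, hd_mu=45.0, hd_kappa=0.0))
        hds = np.arange(0.0, 360.0, 15.0)
        r = rf(0.0, 0.0, hds, 5.0, 0.0)
        assert np.allclose(r, 7.0)

    def test_saturating_speed_form(self):
        m = sim.UnitModel(kind="speed", base_rate=2.0, speed_slope=0.8,
                          speed_form="saturating", saturation_constant=5.0)
        rf = sim.unit_rate_function(m)
        r = rf(0, 0, 0, np.array([0.0, 5.0, 1000.0]), 0)
        rmax = 0.8 * 5.0
        assert np.isclose(r[0], 2.0)
        assert np.isclose(r[2], 2.0 + rmax, atol=1e-6)
        assert r[1] < r[2]

    def test_negative_speed_sign_flips_term(self):
        m = sim.UnitModel(kind="speed", base_rate=10.0, speed_slope=0.3,
                          speed_sign="negative")
        rf = sim.unit_rate_function(m)
        assert rf(0, 0, 0, 20.0, 0) == pytest.approx(4.0)
        assert rf(0, 0, 0, 50.0, 0) == 0.0  # rectified, never negative

    def test_theta_modulation_multiplies_rate(self):
        m = sim.UnitModel(kind="untuned", base_rate=4.0, theta_mod_depth=0.5,
                          theta_freq=8.0)
        rf = sim.unit_rate_function(m)
        assert rf(0, 0, 0, 0, 0.0) == pytest.approx(6.0)  # cos(0)=1
        assert rf(0, 0, 0, 0, 1.0 / 16.0) == pytest.approx(2.0)  # cos(pi)=-1


class TestSpikeSimulation:
    def test_zero_rate_gives_empty_train(self, of_traj):
        rf = sim.unit_rate_function(sim.UnitModel(kind="untuned", base_rate=0))
        train = sim.simulate_spikes(rf, of_traj, seed=1)
        assert train.n_spikes == 0

    def test_constant_rate_poisson_moments(self, of_traj):
        """Thinning at constant 10 Hz yields Poisson counts: mean and
        variance both near rate * duration."""
        rf = sim.unit_rate_function(sim.UnitModel(kind="untuned",
                                                  base_rate=10.0))
        counts = np.array([
            sim.simulate_spikes(rf, of_traj, seed=1000 + s).n_spikes
            for s in range(200)])
        expected = 10.0 * of_traj.duration  # 6000
        assert abs(counts.mean() - expected) < 4 * np.sqrt(expected / 200)
        var_sd = expected * np.sqrt(2.0 / 199)  # sd of sample variance
        assert abs(counts.var(ddof=1) - expected) < 4 * var_sd

    def test_constant_rate_isi_exponential(self, untuned_train):
        isi = np.diff(untuned_train.spike_times)
        res = stats.kstest(isi, "expon", args=(0, 1.0 / 5.0))
        assert res.pvalue > 0.01

    def test_grid_cell_field_count(self, of_traj, grid_model):
        """Spacing-30 lattice must place >= 7 fields inside the 80 cm box
        (lattice geometry oracle: rows every spacing*sqrt(3)/2 = 26 cm)."""
        train = sim.simulate_spikes(sim.unit_rate_function(grid_model),
                                    of_traj, seed=77)
        rm = tuning.build_rate_map(train, of_traj, extent=(80, 80))
        sm = np.where(np.isfinite(rm.smoothed_rate), rm.smoothed_rate, 0.0)
        peaks = (ndimage.maximum_filter(sm, size=3) == sm) \
            & (sm > 0.5 * sm.max())
        _, n_fields = ndimage.label(peaks)
        assert n_fields >= 7

    def test_same_seed_reproduces_train(self, of_traj, grid_model):
        rf = sim.unit_rate_function(grid_model)
        a = sim.simulate_spikes(rf, of_traj, seed=9)
        b = sim.simulate_spikes(rf, of_traj, seed=9)
        assert np.array_equal(a.spike_times, b.spike_times)


class TestLFPSynthesis:
    def test_zero_speed_constant_theta_envelope(self, speeds500):
        still = type(speeds500)(speeds500.bin_start, speeds500.bin_width,
                                np.zeros_like(speeds500.speed),
                                np.zeros_like(speeds500.excluded))
        model = sim.LFPModel(theta_base_amp=0.2, theta_amp_slope=0.05,
                             slow_gamma_amp=0.0, fast_gamma_amp=0.0,
                             slow_gamma_amp_slope=0.0,
                             fast_gamma_amp_slope=0.0,
                             noise_scale=0.0, white_scale=0.0, seed=1)
        sig = sim.synthesize_lfp(model, still)
        assert np.isclose(np.max(np.abs(sig.samples)), 0.2, rtol=1e-3)

    def test_length_matches_duration(self, speeds500):
        sig = sim.synthesize_lfp(sim.LFPModel(seed=2), speeds500, fs=2000.0)
        t_end = speeds500.bin_start[-1] + speeds500.bin_width
        assert sig.samples.size == int(round(t_end * 2000))

    def test_deterministic_under_seed(self, speeds500):
        a = sim.synthesize_lfp(sim.LFPModel(seed=3), speeds500)
        b = sim.synthesize_lfp(sim.LFPModel(seed=3), speeds500)
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_theta_base_freq_rejected(self):
        with pytest.raises(ValueError):
            sim.LFPModel(theta_base_freq=20.0)


class TestGroundTruth:
    def test_manifest_round_trips(self):
        models = {"g0": sim.UnitModel(kind="grid", base_rate=15.0),
                  "u0": sim.UnitModel(kind="untuned", base_rate=3.0)}
        gt = sim.SyntheticGroundTruth(
            arena=sim.open_field(),
            trajectory_params=sim.TrajectoryParams(duration=60.0, seed=4),
            unit_models=models, lfp_model=sim.LFPModel(seed=5),
            spike_seeds={"g0": 10, "u0": 11})
        back = sim.SyntheticGroundTruth.from_dict(gt.to_dict())
        assert back.unit_models == gt.unit_models
        assert back.arena == gt.arena
        assert back.trajectory_params == gt.trajectory_params
        assert back.lfp_model == gt.lfp_model
        assert back.spike_seeds == gt.spike_seeds

    def test_session_reproducible_from_manifest(self):
        models = {"u0": sim.UnitModel(kind="untuned", base_rate=5.0)}
        s1 = sim.simulate_session(sim.open_field(),
                                  sim.TrajectoryParams(duration=60.0, seed=6),
                                  models, seed=7)
        gt = sim.SyntheticGroundTruth.from_dict(s1.ground_truth)
        traj = sim.simulate_trajectory(gt.arena, gt.trajectory_params)
        rf = sim.unit_rate_function(gt.unit_models["u0"])
        train = sim.simulate_spikes(rf, traj, gt.spike_seeds["u0"])
        assert np.array_equal(train.spike_times,
                              s1.spike_trains[0].spike_times)
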