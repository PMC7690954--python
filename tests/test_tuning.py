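"""Rate maps, grid score, spatial information, HD and speed tuning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, special

from gridspeed import preprocess, simulate as sim, tuning
from gridspeed.core import SpeedSeries, SpikeTrain, Trajectory


def make_rate_map(rate, occupancy=None):
    """RateMap stub from explicit per-bin rates (uniform occupancy default)."""
    rate = np.asarray(rate, dtype=float)
    occ = np.ones_like(rate) if occupancy is None \
        else np.asarray(occupancy, dtype=float)
    visited = occ > 0
    ny, nx = rate.shape
    return tuning.RateMap(np.arange(nx + 1) * 3.0, np.arange(ny + 1) * 3.0,
                          occ, rate * occ, rate, rate, visited)


def hex_pattern(n=40, spacing=10.0, orientation=0.0):
    """Analytic three-grating hexagonal field on an n x n grid."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    k = 4 * np.pi / (np.sqrt(3) * spacing)
    s = np.zeros((n, n))
    for j in range(3):
        ang = np.radians(orientation) + j * np.pi / 3
        s += np.cos(k * (np.cos(ang) * xx + np.sin(ang) * yy))
    return np.clip(s, 0, None)


class TestRateMap:
    def test_single_spike_single_bin(self):
        t = np.arange(0, 1.0, 0.04)  # 1 s parked inside one bin
        traj = Trajectory(t, np.full(t.size, 1.5), np.full(t.size, 1.5),
                          np.full(t.size, np.nan))
        train = SpikeTrain("u", np.array([0.5]), 1.0)
        rm = tuning.build_rate_map(train, traj, extent=(9, 9))
        iy, ix = 0, 0
        assert rm.occupancy[iy, ix] == pytest.approx(1.0, rel=0.05)
        assert rm.rate[iy, ix] == pytest.approx(1.0, rel=0.05)

    def test_no_spikes_all_zero(self, of_traj):
        rm = tuning.build_rate_map(SpikeTrain("u", np.empty(0), 600.0),
                                   of_traj, extent=(80, 80))
        assert np.nansum(rm.rate) == 0.0

    def test_occupancy_sums_to_duration(self, of_traj, grid_train):
        rm = tuning.build_rate_map(grid_train, of_traj, extent=(80, 80))
        assert rm.occupancy.sum() == pytest.approx(of_traj.duration, rel=1e-6)

    def test_smoothing_conserves_mean_rate(self, of_traj, untuned_train):
        """Uniform 5 Hz firing: the smoothed map mean stays near 5 Hz."""
        rm = tuning.build_rate_map(untuned_train, of_traj, extent=(80, 80))
        vis = rm.visited
        occ_w = rm.occupancy[vis] / rm.occupancy[vis].sum()
        assert np.sum(occ_w * rm.smoothed_rate[vis]) == pytest.approx(
            5.0, rel=0.1)


class TestAutocorrelation:
    def test_zero_lag_is_one(self, of_traj, grid_train):
        rm = tuning.build_rate_map(grid_train, of_traj, extent=(80, 80))
        ac = tuning.spatial_autocorrelation(rm)
        cy, cx = ac.center
        assert ac.values[cy, cx] == pytest.approx(1.0, abs=1e-9)

    def test_hexagonal_pattern_six_peaks_at_sixty_degrees(self):
        ac = tuning.spatial_autocorrelation(hex_pattern(),
                                            mask=np.ones((40, 40), bool))
        inner, _ = tuning._autocorr_peaks(ac)
        v = np.where(np.isfinite(ac.values), ac.values, -np.inf)
        cy, cx = ac.center
        local = (ndimage.maximum_filter(v, 3) == v) & np.isfinite(ac.values)
        ys, xs = np.nonzero(local & (ac.values > 0.3))
        d = np.hypot(ys - cy, xs - cx)
        ring = (d > inner) & (d < 15)
        assert ring.sum() >= 6
        ang = np.sort(np.degrees(np.arctan2(ys[ring] - cy, xs[ring] - cx))
                      % 360.0)[:6]
        gaps = np.diff(ang)
        assert np.allclose(gaps, 60.0, atol=10.0)

    def test_white_noise_map_uncorrelated_off_center(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(30, 30))
        ac = tuning.spatial_autocorrelation(z, mask=np.ones((30, 30), bool))
        cy, cx = ac.center
        yy, xx = np.indices(ac.values.shape)
        off = np.hypot(yy - cy, xx - cx) > 2
        vals = ac.values[off & np.isfinite(ac.values)]
        assert np.abs(vals).mean() < 0.15

    def test_sparse_lags_masked(self):
        z = np.arange(25.0).reshape(5, 5)
        ac = tuning.spatial_autocorrelation(z, mask=np.ones((5, 5), bool),
                                            min_overlap=20)
        # on a 5x5 map only the centre (25) and the four unit shifts (20)
        # retain >= 20 overlapping bins
        assert np.isfinite(ac.values).sum() == 5
        cy, cx = ac.center
        assert np.isfinite(ac.values[cy, cx])
        assert not np.isfinite(ac.values[cy + 1, cx + 1])


class TestGridScore:
    def test_ideal_hexagonal_pattern_scores_high(self):
        ac = tuning.spatial_autocorrelation(hex_pattern(),
                                            mask=np.ones((40, 40), bool))
        gs = tuning.grid_score(ac)
        assert gs.g > 1.0

    def test_isotropic_gaussian_scores_near_zero(self):
        yy, xx = np.mgrid[0:31, 0:31].astype(float)
        z = np.exp(-((xx - 15) ** 2 + (yy - 15) ** 2) / 40.0)
        ac = tuning.spatial_autocorrelation(z, mask=np.ones((31, 31), bool))
        gs = tuning.grid_score(ac)
        assert abs(gs.g) < 0.2

    def test_square_symmetry_scores_negative(self):
        """A 90-degree-symmetric checkerboard maximises the 90-degree
        rotation correlation, driving g below zero."""
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        z = np.cos(2 * np.pi * xx / 10) + np.cos(2 * np.pi * yy / 10)
        ac = tuning.spatial_autocorrelation(z, mask=np.ones((40, 40), bool))
        assert tuning.grid_score(ac).g < 0.0

    def test_invariant_to_rate_scaling(self, of_traj, grid_train):
        rm = tuning.build_rate_map(grid_train, of_traj, extent=(80, 80))
        g1 = tuning.grid_score(tuning.spatial_autocorrelation(rm)).g
        scaled = make_rate_map(np.where(rm.visited, rm.smoothed_rate, 0) * 3.7,
                               occupancy=rm.occupancy)
        g2 = tuning.grid_score(tuning.spatial_autocorrelation(scaled)).g
        assert g2 == pytest.approx(g1, abs=0.05)

    def test_invariant_to_quarter_turn_of_arena(self, of_traj, grid_train):
        g1 = tuning.grid_score(tuning.spatial_autocorrelation(
            tuning.build_rate_map(grid_train, of_traj, extent=(80, 80)))).g
        rot = Trajectory(of_traj.timestamps, of_traj.y,
                         80.0 - of_traj.x, of_traj.hd_deg)
        g2 = tuning.grid_score(tuning.spatial_autocorrelation(
            tuning.build_rate_map(grid_train, rot, extent=(80, 80)))).g
        assert g2 == pytest.approx(g1, abs=0.15)


class TestSpatialInformation:
    def test_uniform_rate_zero_bits(self):
        rm = make_rate_map(np.full((4, 4), 3.0))
        assert tuning.spatial_information(rm) == pytest.approx(0.0, abs=1e-12)

    def test_single_active_bin_log2_n(self):
        rate = np.zeros((4, 4))
        rate[2, 1] = 16.0
        rm = make_rate_map(rate)
        assert tuning.spatial_information(rm) == pytest.approx(4.0)

    def test_two_bin_closed_form(self):
        rm = make_rate_map(np.array([[2.0, 0.0]]))
        assert tuning.spatial_information(rm) == pytest.approx(1.0)

    def test_zero_mean_rate_undefined(self):
        with pytest.raises(tuning.UndefinedSIError):
            tuning.spatial_information(make_rate_map(np.zeros((3, 3))))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(9)
        rate = rng.gamma(2.0, 2.0, (6, 6))
        base = tuning.spatial_information(make_rate_map(rate))
        scaled = tuning.spatial_information(make_rate_map(rate * scale))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestHDScore:
    def test_untuned_unit_near_zero(self, of_traj, untuned_train):
        assert tuning.hd_score(untuned_train, of_traj).mvl < 0.1

    def test_single_bin_mass_near_one(self):
        t = np.arange(0, 120, 0.04)
        hd = np.full(t.size, np.nan)
        hd[:] = (t * 60.0) % 360.0  # sweeps the circle uniformly
        traj = Trajectory(t, np.zeros(t.size), np.zeros(t.size), hd)
        spike_at = np.abs(((hd - 90.0) + 180) % 360 - 180) < 1.5
        train = SpikeTrain("u", t[spike_at], 120.0)
        res = tuning.hd_score(train, traj)
        assert res.mvl > 0.95
        assert res.preferred_deg == pytest.approx(90.0, abs=5.0)

    def test_von_mises_kappa_two_bessel_ratio(self, of_traj, hd_train):
        """kappa=2 tuning must recover R ~ I1(2)/I0(2) ~ 0.698."""
        expected = special.i1(2.0) / special.i0(2.0)
        res = tuning.hd_score(hd_train, of_traj)
        assert res.mvl == pytest.approx(expected, abs=0.05)
        assert res.preferred_deg == pytest.approx(90.0, abs=10.0)

    def test_rotation_invariance_of_mvl(self, of_traj, hd_train):
        rolled = Trajectory(of_traj.timestamps, of_traj.x, of_traj.y,
                            (of_traj.hd_deg + 77.0) % 360.0)
        a = tuning.hd_score(hd_train, of_traj)
        b = tuning.hd_score(hd_train, rolled)
        assert b.mvl == pytest.approx(a.mvl, abs=0.02)

    def test_empty_hd_series_raises(self, untuned_train):
        t = np.arange(0, 600, 0.04)
        traj = Trajectory(t, np.zeros(t.size), np.zeros(t.size),
                          np.full(t.size, np.nan))
        with pytest.raises(ValueError):
            tuning.hd_score(untuned_train, traj)


class TestSpeedScore:
    def test_linear_rate_high_correlation(self, speeds40):
        """Rate = 2 + 0.5 speed plus small noise correlates near-perfectly:
        build a train whose per-bin counts follow the rate deterministically
        (only quantisation noise)."""
        rng = np.random.default_rng(30)
        scale = 20.0  # spikes per Hz per bin multiplier
        expected = (2.0 + 0.5 * speeds40.speed) * speeds40.bin_width * scale
        counts = np.floor(np.cumsum(expected)).astype(int)
        counts = np.diff(np.concatenate([[0], counts]))
        times = np.repeat(speeds40.bin_center, counts)
        train = SpikeTrain("u", times, float(times.max() + 1.0))
        sc = tuning.speed_score(train, speeds40)
        assert sc.valid
        assert sc.r > 0.95
        assert sc.z > 1.8

    def test_constant_rate_invalid(self, speeds40):
        # pathological zero-variance rate: no spikes at all
        sc = tuning.speed_score(SpikeTrain("u", np.empty(0), 600.0), speeds40)
        assert not sc.valid
        assert np.isnan(sc.z)

    def test_negative_speed_cell(self, of_traj, speeds40):
        model = sim.UnitModel(kind="speed", base_rate=30.0, speed_slope=1.0,
                              speed_sign="negative")
        train = sim.simulate_spikes(sim.unit_rate_function(model), of_traj,
                                    seed=32)
        sc = tuning.speed_score(train, speeds40)
        assert sc.r < 0 and sc.z < 0

    def test_z_is_atanh_of_r(self, of_traj, speeds40, speed_train):
        sc = tuning.speed_score(speed_train, speeds40)
        assert sc.z == pytest.approx(np.arctanh(sc.r))

    def test_slope_recovery(self, of_traj, speeds40, speed_train):
        sc = tuning.speed_score(speed_train, speeds40)
        assert sc.slope == pytest.approx(0.5, rel=0.15)


class TestSpeedRelationship:
    @pytest.mark.parametrize("form", ["linear", "saturating"])
    def test_form_recovery(self, of_traj, speeds40, form):
        correct = 0
        for seed in range(10):
            model = sim.UnitModel(kind="speed", base_rate=2.0,
                                  speed_slope=0.8, speed_form=form,
                                  saturation_constant=5.0)
            train = sim.simulate_spikes(sim.unit_rate_function(model),
                                        of_traj, seed=40 + seed)
            rel = tuning.classify_speed_relationship(train, speeds40)
            correct += rel["form"] == form
        assert correct >= 9

    def test_negative_unit_sign(self, of_traj, speeds40):
        model = sim.UnitModel(kind="speed", base_rate=10.0, speed_slope=0.3,
                              speed_sign="negative")
        train = sim.simulate_spikes(sim.unit_rate_function(model), of_traj,
                                    seed=50)
        rel = tuning.classify_speed_relationship(train, speeds40)
        assert rel["sign"] == "negative"
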