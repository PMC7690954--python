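"""Classification assembly and the group statistics (chi-square, U, Wilcoxon)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gridspeed import stats as gstats


def brute_force_chi2(table):
    """Independent oracle: sum (O-E)^2 / E over the four cells."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / total
            chi2 += (t[i, j] - e) ** 2 / e
    return chi2


def brute_force_u(a, b):
    """Independent oracle: count pairs won by the first sample (ties half)."""
    u = 0.0
    for x in a:
        for y in b:
            u += (x > y) + 0.5 * (x == y)
    return u


class TestChiSquare:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    def test_matches_bruteforce(self, cells):
        table = [cells[:2], cells[2:]]
        chi2, df, p = gstats.chi_square_2x2(table)
        assert chi2 == pytest.approx(brute_force_chi2(table))
        assert df == 1

    def test_independence_gives_zero(self):
        chi2, _, p = gstats.chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            gstats.chi_square_2x2([[0, 0], [5, 5]])


class TestMannWhitney:
    def test_identical_small_samples_half_product(self):
        u, _ = gstats.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n1 n2 / 2

    def test_fully_separated(self):
        u, p = gstats.mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p < 0.2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.lists(st.integers(0, 9), min_size=1, max_size=5),
           b=st.lists(st.integers(0, 9), min_size=1, max_size=5))
    def test_matches_enumeration_on_small_samples(self, a, b):
        u, _ = gstats.mann_whitney_u(a, b, convention="first")
        assert u == pytest.approx(brute_force_u(a, b))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                      max_size=8),
           b=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                      max_size=8))
    def test_u_complement_identity(self, a, b):
        u_ab, _ = gstats.mann_whitney_u(a, b, convention="first")
        u_ba, _ = gstats.mann_whitney_u(b, a, convention="first")
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            gstats.mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_antisymmetric_differences_zero_z(self):
        z, p = gstats.wilcoxon_signed_rank([-3, -2, -1, 1, 2, 3])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_positive_is_maximal_over_sign_flips(self):
        """Exhaustive sign-flip oracle: no assignment of signs to 10 ranks
        yields a larger Z than the all-positive pattern."""
        d = np.arange(1.0, 11.0)
        z_obs, _ = gstats.wilcoxon_signed_rank(d)
        zs = []
        for signs in itertools.product([-1, 1], repeat=10):
            z, _ = gstats.wilcoxon_signed_rank(d * np.array(signs))
            zs.append(z)
        assert z_obs == pytest.approx(max(zs))

    def test_single_nonzero_difference_degenerate(self):
        assert gstats.wilcoxon_signed_rank([0.0, 0.0, 1.5]) == (0.0, 1.0)

    def test_all_zero_degenerate(self):
        assert gstats.wilcoxon_signed_rank([0.0, 0.0]) == (0.0, 1.0)


class TestClassification:
    def test_conjunctive_label(self):
        uc = gstats.classify_unit("u", {"grid": True, "hd": True,
                                        "speed": True})
        assert uc.label == "conjunctive"
        assert uc.n_classes == 3

    def test_unclassified(self):
        assert gstats.classify_unit("u", {}).label == "unclassified"

    def test_single_class(self):
        assert gstats.classify_unit("u", {"hd": True}).label == "single-class"

    def test_grid_suppresses_spatial_nongrid(self):
        uc = gstats.classify_unit("u", {"grid": True, "spatial_nongrid": True})
        assert uc.flags["grid"] and not uc.flags["spatial_nongrid"]
        assert uc.label == "single-class"

    def test_order_invariance_of_proportions(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "is_grid": rng.uniform(size=40) < 0.3,
            "is_speed": rng.uniform(size=40) < 0.5,
            "grid_score": rng.normal(size=40),
        })
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = gstats.group_report(df, df)["proportions"]
        b = gstats.group_report(shuffled, shuffled)["proportions"]
        pd.testing.assert_frame_equal(a, b)


class TestGroupReport:
    def _cohort(self, seed, n=60, speed_frac=0.5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "grid_score": rng.normal(0.1, 0.3, n),
            "si": rng.gamma(2.0, 0.25, n),
            "hd_score": rng.beta(2, 12, n),
            "speed_z": rng.normal(0.1, 0.2, n),
            "tmi": rng.gamma(3.0, 3.0, n),
            "mean_rate": rng.gamma(2.0, 2.0, n),
            "is_grid": rng.uniform(size=n) < 0.25,
            "is_hd": rng.uniform(size=n) < 0.15,
            "is_speed": rng.uniform(size=n) < speed_frac,
            "speed_sign": rng.choice(["positive", "negative"], n,
                                     p=[0.85, 0.15]),
        })

    def test_identical_cohorts_null_statistics(self):
        df = self._cohort(3)
        rep = gstats.group_report(df, df, labels=("WT", "TG"))
        assert np.allclose(rep["proportions"]["chi2"].astype(float), 0.0)
        n2 = len(df) ** 2
        assert np.allclose(rep["scores"]["U"].astype(float), n2 / 2)

    def test_negative_speed_proportion_reported(self):
        rep = gstats.group_report(self._cohort(4), self._cohort(5))
        assert "negative_speed_of_modulated" in rep["proportions"].index

    def test_mean_speed_comparison(self):
        rep = gstats.group_report(
            self._cohort(6), self._cohort(7),
            session_speeds=([7.5, 8.1, 8.4], [11.0, 12.5, 10.9]))
        assert rep["mean_speed_test"]["p"] < 0.05
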