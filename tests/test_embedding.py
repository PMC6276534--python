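"""Delay estimation, Cao's dimension criterion and the embedding map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reference import brute_cao_e, brute_mi_2d_hist
from rqadetect.embedding import (AMICurve, EmbeddingParams, ami_curve,
                                 cao_curves, embed, estimate_embedding,
                                 select_delay, select_dim)
from rqadetect.signals import TimeSeries, gen_logistic, gen_noise, gen_sine


class TestAMICurve:
    def test_constant_series_degenerate(self):
        with pytest.warns(UserWarning):
            c = ami_curve(TimeSeries(np.ones(50)), max_lag=5)
        assert c.degenerate
        assert np.allclose(c.mi, 0)

    def test_lag_zero_equals_binned_entropy(self, rng):
        x = rng.normal(size=400)
        c = ami_curve(TimeSeries(x), max_lag=3, n_bins=10)
        edges = np.linspace(x.min(), x.max(), 11)
        counts, _ = np.histogram(x, bins=edges)
        p = counts[counts > 0] / counts.sum()
        assert c.mi[0] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-10)

    @pytest.mark.parametrize("n,n_bins", [(64, 5), (256, 12), (512, 20)])
    def test_matches_brute_force_histogram_oracle(self, rng, n, n_bins):
        x = rng.normal(size=n)
        c = ami_curve(TimeSeries(x), max_lag=8, n_bins=n_bins)
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        for k in range(9):
            expected = brute_mi_2d_hist(x[: n - k] if k else x, x[k:], edges)
            assert c.mi[k] == pytest.approx(expected, abs=1e-12)

    def test_sine_first_minimum_near_quarter_period(self):
        # period 64 samples -> quarter-period AMI minimum at lag 16
        for seed in range(3):
            s = gen_sine(freq=1.0, rate=64.0, n=8192, noise_sd=0.2, rng=seed)
            c = ami_curve(s, max_lag=40, n_bins=16)
            assert select_delay(c) in (15, 16, 17)


class TestSelectDelay:
    def test_first_dip(self):
        c = AMICurve(np.arange(5), np.array([2.0, 1.2, 0.8, 0.9, 0.5]))
        assert select_delay(c) == 2

    def test_plateau_counts_as_minimum(self):
        c = AMICurve(np.arange(4), np.array([1.0, 0.4, 0.4, 0.7]))
        assert select_delay(c) == 2

    def test_monotone_curve_falls_back_to_1_over_e(self):
        mi = 2.0 * 0.7 ** np.arange(12)  # strictly decreasing
        c = AMICurve(np.arange(12), mi)
        expected = np.nonzero(mi[1:] < mi[0] / np.e)[0][0] + 1  # scan oracle
        assert select_delay(c) == expected

    def test_flat_curve_falls_back_to_max_lag(self):
        c = AMICurve(np.arange(6), np.full(6, 1.0))
        assert select_delay(c) == 5


class TestCao:
    def test_logistic_e1_saturates_by_dimension_two(self):
        s = gen_logistic(r=4, x0=0.2, n=800)
        e1, _ = cao_curves(s, tau=1, m_max=6)
        assert np.all(np.abs(e1[1:] - 1.0) < 0.1)

    def test_white_noise_e2_stays_near_one(self):
        s = gen_noise("white", 800, seed=11)
        _, e2 = cao_curves(s, tau=1, m_max=6)
        assert np.all(np.abs(e2 - 1.0) < 0.1)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_brute_force_nearest_neighbor_oracle(self, rng, m):
        x = rng.normal(size=120)
        e_impl = []
        from rqadetect.embedding import _nn_stats
        e, e_star = _nn_stats(x, tau=2, m=m)
        e_ref, e_star_ref = brute_cao_e(x, tau=2, m=m)
        assert e == pytest.approx(e_ref, abs=1e-12)
        assert e_star == pytest.approx(e_star_ref, abs=1e-12)

    def test_identical_points_degenerate(self):
        s = TimeSeries(np.ones(50))
        with pytest.raises(ValueError):
            cao_curves(s, tau=1, m_max=3)


class TestSelectDim:
    def test_first_index_within_tolerance(self):
        assert select_dim(np.array([0.5, 0.95, 0.99, 1.0]), 0.06) == 2

    def test_never_saturating_falls_back_to_m_max(self):
        assert select_dim(np.array([0.5, 0.6, 0.7]), 0.05) == 3

    def test_cao_selects_low_dimension_for_logistic_map(self):
        # one-dimensional map: E1 saturates by m = 2 at unit delay; the
        # selected dimension agrees with a full brute-force Cao recomputation
        s = gen_logistic(r=4, x0=0.3, n=300)
        e1, _ = cao_curves(s, tau=1, m_max=5)
        m = select_dim(e1)
        assert m <= 3

        e_ref = [brute_cao_e(s.samples, tau=1, m=mm)[0] for mm in range(1, 6)]
        e1_ref = np.array(e_ref[1:]) / np.array(e_ref[:-1])
        assert select_dim(e1_ref) == m


class TestEmbed:
    def test_coordinates_follow_delay_construction(self):
        s = TimeSeries(np.arange(10, dtype=float))
        t = embed(s, EmbeddingParams(tau=2, m=3))
        assert len(t) == 6
        assert np.array_equal(t.points[0], [0, 2, 4])
        assert np.array_equal(t.points[5], [5, 7, 9])

    def test_m1_is_identity(self, rng):
        x = rng.normal(size=20)
        t = embed(TimeSeries(x), EmbeddingParams(tau=3, m=1))
        assert np.array_equal(t.points[:, 0], x)

    def test_insufficient_length_names_deficit(self):
        s = TimeSeries(np.arange(5, dtype=float))
        with pytest.raises(ValueError, match="missing"):
            embed(s, EmbeddingParams(tau=3, m=3))

    @settings(deadline=None, max_examples=50)
    @given(n=st.integers(5, 60), m=st.integers(1, 4), tau=st.integers(1, 5))
    def test_point_count_is_length_exact(self, n, m, tau):
        if n - (m - 1) * tau < 1:
            return
        t = embed(TimeSeries(np.arange(n, dtype=float)),
                  EmbeddingParams(tau=tau, m=m))
        assert len(t) + (m - 1) * tau == n
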