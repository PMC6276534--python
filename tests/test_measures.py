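"""The twelve recurrence-quantification measures against brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trajectory, random_symmetric_rp
from reference import brute_det, brute_recurrence_times, brute_transitivity
from rqadetect.measures import (FeatureConfig, RQAConfig, det, entr,
                                extract_features, l_max, l_mean, lam,
                                recurrence_times,
                                recurrence_times_from_matrix, rpde, rr, t1,
                                t2, transitivity, tt, v_max)
from rqadetect.recurrence import (AdjacencyMatrix, LineHistogram,
                                  RecurrenceMatrix, adjacency,
                                  diagonal_histogram, vertical_histogram)
from rqadetect.signals import TimeSeries, gen_noise, gen_sine


def rp_from(matrix, eps=1.0):
    return RecurrenceMatrix(matrix, epsilon=eps)


def dhist(counts):
    return LineHistogram("diagonal", counts, loi_excluded=True)


def vhist(counts):
    return LineHistogram("vertical", counts)


class TestPointDensity:
    def test_all_ones_and_identity(self):
        assert rr(rp_from(np.ones((6, 6)))) == 1.0
        assert rr(rp_from(np.eye(8))) == pytest.approx(1 / 8)

    def test_forced_three_point_matrix(self):
        R = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        assert rr(rp_from(R)) == pytest.approx(5 / 9)


class TestDiagonalMeasures:
    def test_det_formula(self):
        assert det(dhist({1: 2, 2: 2}), l_min=2) == pytest.approx(4 / 6)

    def test_det_saturates_when_all_lines_qualify(self):
        assert det(dhist({3: 4, 5: 1}), l_min=2) == 1.0

    def test_l_mean_and_l_max(self):
        h = dhist({2: 1, 4: 1})
        assert l_mean(h, l_min=2) == pytest.approx(3.0)
        assert l_max(h) == 4

    def test_empty_histogram_degenerates_to_zero(self):
        h = dhist({})
        assert l_mean(h, 2) == 0.0
        assert l_max(h) == 0
        assert det(h, 2) == 0.0
        assert entr(h, 2) == 0.0

    def test_entr_single_length_is_zero(self):
        assert entr(dhist({4: 7}), 2) == 0.0

    def test_entr_uniform_two_lengths_is_ln2(self):
        assert entr(dhist({2: 1, 3: 1}), 2) == pytest.approx(math.log(2))

    def test_entr_matches_direct_shannon_oracle(self, rng):
        for _ in range(20):
            lengths = rng.integers(1, 9, size=6)
            counts = {int(l): int(c) for l, c in
                      zip(*np.unique(lengths, return_counts=True))}
            total = sum(c for l, c in counts.items() if l >= 2)
            expected = 0.0
            for l, c in counts.items():
                if l >= 2 and total:
                    p = c / total
                    expected -= p * math.log(p)
            assert entr(dhist(counts), 2) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(3, 16), seed=st.integers(0, 10_000))
    def test_det_matches_point_classification_oracle(self, n, seed):
        R = random_symmetric_rp(np.random.default_rng(seed), n)
        h = diagonal_histogram(rp_from(R), exclude_loi=True)
        assert det(h, 2) == pytest.approx(brute_det(R, 2), abs=1e-12)


class TestVerticalMeasures:
    def test_identity_matrix(self):
        h = vertical_histogram(rp_from(np.eye(5)))
        assert lam(h, 2) == 0.0
        assert tt(h, 2) == 0.0
        assert v_max(h) == 1

    def test_all_ones_saturation(self):
        h = vertical_histogram(rp_from(np.ones((6, 6))))
        assert lam(h, 2) == 1.0
        assert tt(h, 2) == 6.0
        assert v_max(h) == 6

    def test_formula_on_mixed_histogram(self):
        h = vhist({1: 3, 2: 2, 5: 1})
        assert lam(h, 2) == pytest.approx(9 / 12)
        assert tt(h, 2) == pytest.approx(9 / 3)


class TestRecurrenceTimes:
    def test_periodic_orbit_t2_equals_period(self):
        angles = 2 * np.pi * np.arange(40) / 8  # exact period-8 orbit
        pts = np.column_stack([np.cos(angles), np.sin(angles)])
        t = make_trajectory(pts)
        times = recurrence_times(t, r=0.1)
        assert times.t2_times.size > 0
        assert np.all(times.t2_times == 8)
        assert t2(times) == 8.0

    def test_sojourn_gaps_in_t1_only(self):
        # one reference row: inside for 3 consecutive steps then re-entry
        inside = np.array([[1, 1, 1, 0, 0, 1]], dtype=bool)
        times = recurrence_times_from_matrix(inside)
        assert sorted(times.t1_times.tolist()) == [1, 1, 3]
        assert times.t2_times.tolist() == [5]

    def test_empty_sets_give_zero_means(self):
        times = recurrence_times_from_matrix(np.eye(4, dtype=bool))
        assert t1(times) == 0.0 or times.t1_times.size == 0
        assert t2(times) == 0.0

    def test_noise_t1_below_t2(self, rng):
        pts = rng.normal(size=(300, 2))
        t = make_trajectory(pts)
        times = recurrence_times(t, r=0.5)
        assert t1(times) < t2(times)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_matches_entry_event_state_machine(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(50, 2))
        t = make_trajectory(pts)
        times = recurrence_times(t, r=0.8)
        ref_t1, ref_t2 = brute_recurrence_times(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=2) <= 0.8)
        assert sorted(times.t1_times.tolist()) == sorted(ref_t1)
        assert sorted(times.t2_times.tolist()) == sorted(ref_t2)


class TestRPDE:
    def test_all_equal_times_is_zero(self):
        assert rpde(np.full(50, 7)) == 0.0

    def test_uniform_times_is_one(self):
        times = np.repeat(np.arange(1, 11), 5)
        assert rpde(times) == pytest.approx(1.0)

    def test_empty_set_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert rpde(np.array([])) == 0.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            times = rng.integers(1, 30, size=rng.integers(1, 100))
            assert 0.0 <= rpde(times) <= 1.0


class TestTransitivity:
    def test_complete_graph(self):
        A = ~np.eye(4, dtype=bool)
        assert transitivity(AdjacencyMatrix(A)) == 1.0

    def test_star_graph_has_no_triangles(self):
        A = np.zeros((4, 4), dtype=bool)
        A[0, 1:] = A[1:, 0] = True
        assert transitivity(AdjacencyMatrix(A)) == 0.0

    def test_empty_graph_is_zero(self):
        assert transitivity(AdjacencyMatrix(np.zeros((5, 5), bool))) == 0.0

    @settings(deadline=None, max_examples=30)
    @given(n=st.integers(3, 20), seed=st.integers(0, 10_000))
    def test_matches_triple_enumeration_and_networkx(self, n, seed):
        rng = np.random.default_rng(seed)
        A = random_symmetric_rp(rng, n)
        np.fill_diagonal(A, False)
        ours = transitivity(AdjacencyMatrix(A))
        assert ours == pytest.approx(brute_transitivity(A), abs=1e-12)
        assert ours == pytest.approx(
            nx.transitivity(nx.from_numpy_array(A)), abs=1e-12)


class TestExtractFeatures:
    def test_sine_block_is_deterministic_and_periodic(self):
        blk = gen_sine(freq=3.5, rate=173.61, n=256)
        fv = extract_features(blk)
        assert fv.det > 0.95
        assert fv.rpde < 0.2

    def test_noise_block_less_deterministic_than_sine(self):
        blk = gen_sine(freq=3.5, rate=173.61, n=256)
        noise = TimeSeries(gen_noise("white", 256, seed=8).samples,
                           rate=173.61)
        assert extract_features(noise).det < extract_features(blk).det

    def test_constant_block_degenerate_path(self):
        fv = extract_features(TimeSeries(np.full(256, 3.0), rate=173.61))
        assert fv.rr == 1.0
        assert fv.rpde == 0.0
        assert fv.trans == 1.0
        assert "degenerate" in fv.flags

    def test_ratio_measures_bounded(self, rng):
        for _ in range(5):
            blk = TimeSeries(rng.normal(size=200))
            fv = extract_features(blk)
            for name in ("rr", "det", "lam", "rpde", "trans"):
                assert 0.0 <= getattr(fv, name) <= 1.0

    def test_deterministic_for_fixed_config(self, rng):
        x = rng.normal(size=256)
        a = extract_features(TimeSeries(x.copy()))
        b = extract_features(TimeSeries(x.copy()))
        assert np.array_equal(a.values(), b.values())
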