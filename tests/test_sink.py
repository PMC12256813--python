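import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sinkindex.dnm import DNM, fit_dnm
from sinkindex.exceptions import EmptyModelError, ValidationError
from sinkindex.io import CANONICAL_19, Recording
from sinkindex.sink import (
    CPO_CHANNELS,
    FT_CHANNELS,
    RegionScheme,
    normalized_ranks,
    row_col_norms,
    si_bounds,
    sink_index_of_matrix,
    sink_map,
    subject_marker,
)
from sinkindex.synth import PlantedNetwork, make_planted_A, simulate_recording

SQRT2 = math.sqrt(2.0)


def _dnm_from_A(A_list, labels=None):
    A = np.asarray(A_list, dtype=float)
    n = A.shape[1]
    labels = labels or list(CANONICAL_19[:n])
    return DNM(A, 31, 125.0, 250.0, labels, [None] * A.shape[0],
               np.ones(A.shape[0], dtype=bool))


class TestRowColNorms:
    def test_identity(self):
        r, c = row_col_norms(np.eye(4))
        np.testing.assert_allclose(r, 1.0)
        np.testing.assert_allclose(c, 1.0)

    def test_single_entry(self):
        r, c = row_col_norms(np.array([[0, 0], [0.9, 0]]))
        np.testing.assert_allclose(r, [0.0, 0.9])
        np.testing.assert_allclose(c, [0.9, 0.0])

    def test_against_elementwise_oracle(self, rng):
        A = rng.normal(0, 1, (5, 5))
        r, c = row_col_norms(A)
        r_brute = [math.sqrt(sum(A[i, j] ** 2 for j in range(5))) for i in range(5)]
        c_brute = [math.sqrt(sum(A[i, j] ** 2 for i in range(5))) for j in range(5)]
        np.testing.assert_allclose(r, r_brute, atol=1e-12)
        np.testing.assert_allclose(c, c_brute, atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            row_col_norms(np.zeros((3, 4)))


class TestNormalizedRanks:
    def test_simple(self):
        np.testing.assert_allclose(normalized_ranks([3, 1, 2]), [1.0, 1 / 3, 2 / 3])

    def test_all_equal_stable_ties(self):
        np.testing.assert_allclose(normalized_ranks([5, 5, 5, 5]),
                                   [0.25, 0.5, 0.75, 1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            normalized_ranks([1.0, np.nan, 2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(2, 30),
                      elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_permutation_and_monotone_against_sort_oracle(self, values):
        ranks = normalized_ranks(values)
        n = values.size
        # always a permutation of {1/N, ..., 1}
        assert sorted(np.round(ranks * n).astype(int)) == list(range(1, n + 1))
        # monotone w.r.t. a sort-based oracle (strictly ordered pairs only)
        order = np.argsort(values, kind="stable")
        for a, b in zip(order, order[1:]):
            if values[a] < values[b]:
                assert ranks[a] < ranks[b]


class TestSinkIndexOfMatrix:
    def test_two_node_ideal_sink(self):
        si = sink_index_of_matrix(np.array([[0, 0], [0.9, 0]]))
        assert si[1] == pytest.approx(SQRT2, abs=1e-5)          # 1.41421
        assert si[0] == pytest.approx(SQRT2 - math.sqrt(0.5), abs=1e-5)  # 0.70711

    def test_four_node_sink_and_source(self):
        # node 2 (index 1): near-zero column, large row -> sink;
        # node 3 (index 2): the reverse -> source
        A = np.array([
            [0.30, 0.00, 0.80, 0.10],
            [0.70, 0.30, 0.90, 0.60],
            [0.05, 0.00, 0.30, 0.00],
            [0.10, 0.00, 0.70, 0.30],
        ])
        si = sink_index_of_matrix(A)
        assert np.argmax(si) == 1
        assert np.argmin(si) == 2

    def test_n19_mid_rank_closed_form(self):
        """A channel with both normalized ranks 10/19 sits at distance
        (9/19)sqrt(2) from the ideal sink: SI = sqrt(2) * 10/19 = 0.74432."""
        rr = cr = 10 / 19
        si = SQRT2 - math.hypot(rr - 1, cr - 1 / 19)
        assert si == pytest.approx(0.74432, abs=1e-5)
        assert si == pytest.approx(SQRT2 * 10 / 19, abs=1e-12)

    def test_bounds_enumeration(self):
        """Exhaustive enumeration of the rank grid reproduces the
        closed-form attainable range."""
        for n in (2, 5, 19):
            grid = np.arange(1, n + 1) / n
            vals = [SQRT2 - math.hypot(rr - 1, cr - 1 / n)
                    for rr in grid for cr in grid]
            lo, hi = si_bounds(n)
            assert min(vals) == pytest.approx(lo, abs=1e-12)
            assert max(vals) == pytest.approx(hi, abs=1e-12)

    def test_transpose_antisymmetry(self, rng):
        """Transposing A swaps each channel's row/column ranks; a pure sink
        becomes a pure source."""
        A = make_planted_A(10, [4], 1.0, seed=1)
        r, c = row_col_norms(A)
        rT, cT = row_col_norms(A.T)
        np.testing.assert_allclose(r, cT)
        np.testing.assert_allclose(c, rT)
        si = sink_index_of_matrix(A)
        siT = sink_index_of_matrix(A.T)
        assert np.argmax(si) == 4
        assert np.argmin(siT) == 4

    def test_unique_top_ranks_for_distinct_norms(self, rng):
        A = rng.normal(0, 1, (7, 7))
        r, c = row_col_norms(A)
        rr, cr = normalized_ranks(r), normalized_ranks(c)
        assert np.sum(rr == 1.0) == 1
        assert np.sum(cr == 1.0) == 1


class TestSinkMap:
    def test_identical_windows_constant_map(self):
        A = make_planted_A(5, [1], 0.8, seed=0)
        dnm = _dnm_from_A([A] * 10)
        smap = sink_map(dnm)
        for k in range(10):
            np.testing.assert_allclose(smap.si[:, k], smap.si[:, 0])
        np.testing.assert_allclose(smap.time_avg_si, smap.si[:, 0])

    def test_channel_permutation_equivariance(self, rng):
        A = rng.normal(0, 1, (6, 6))
        labels = list(CANONICAL_19[:6])
        perm = rng.permutation(6)
        dnm1 = _dnm_from_A([A], labels)
        dnm2 = _dnm_from_A([A[np.ix_(perm, perm)]], [labels[i] for i in perm])
        si1 = sink_map(dnm1).si[:, 0]
        si2 = sink_map(dnm2).si[:, 0]
        np.testing.assert_allclose(si2, si1[perm])

    def test_bounds_hold_everywhere(self, noise_recording):
        smap = sink_map(fit_dnm(noise_recording))
        lo, hi = si_bounds(19)
        assert smap.si.min() >= lo - 1e-12
        assert smap.si.max() <= hi + 1e-12
        assert smap.si.min() >= 0.0744 - 1e-4 and smap.si.max() <= 1.4143

    def test_no_valid_windows_rejected(self):
        dnm = _dnm_from_A([np.eye(3)])
        dnm.valid[:] = False
        with pytest.raises(EmptyModelError):
            sink_map(dnm)

    def test_sink_planted_in_second_half_only(self):
        """A sink switched on at the midpoint raises that channel's mean SI
        over second-half windows above its first-half mean."""
        A_flat = make_planted_A(8, [], 0.0, seed=5)
        A_sink = make_planted_A(8, [3], 0.9, seed=5)
        net = PlantedNetwork([(A_flat, 20.0), (A_sink, 20.0)], {"P4": 0.9},
                             1.0, 250.0, seed=11)
        rec = simulate_recording(net, 40.0)
        smap = sink_map(fit_dnm(rec))
        mid = smap.si.shape[1] // 2
        assert smap.si[3, mid + 2 :].mean() > smap.si[3, : mid - 2].mean()


class TestSubjectMarker:
    def test_uniform_map_gives_ratio_one(self):
        dnm = _dnm_from_A([np.eye(19)])
        smap = sink_map(dnm)
        smap.time_avg_si = np.full(19, 0.9)
        marker = subject_marker(smap, subject_id="u")
        assert marker.si_ft == pytest.approx(0.9)
        assert marker.si_cpo == pytest.approx(0.9)
        assert marker.si_ratio == pytest.approx(1.0)

    def test_ft_double_cpo(self):
        dnm = _dnm_from_A([np.eye(19)])
        smap = sink_map(dnm)
        labels = np.asarray(smap.channel_labels)
        vals = np.where(np.isin(labels, FT_CHANNELS), 1.2, 0.6)
        smap.time_avg_si = vals
        marker = subject_marker(smap)
        assert marker.si_ratio == pytest.approx(2.0)

    def test_region_scheme_covers_montage(self):
        scheme = RegionScheme()
        assert len(scheme.ft_channels) == 8
        assert len(scheme.cpo_channels) == 11
        assert set(CANONICAL_19) == scheme.ft_channels | scheme.cpo_channels
        assert "Fz" in scheme.cpo_channels  # frontal-midline lives in CPO here

    def test_uncovered_channel_rejected(self):
        dnm = _dnm_from_A([np.eye(3)], ["Cz", "Pz", "Xx"])
        smap = sink_map(dnm)
        with pytest.raises(ValidationError):
            subject_marker(smap)
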