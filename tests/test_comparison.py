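import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtrflp import comparison
from dtrflp.comparison import (
    apply_shift,
    cross_correlate,
    match_peaks,
    mirror_data,
    profile_to_vector,
)
from dtrflp.seqio import TRFLPProfile


def brute_force_xcorr(d, e, max_lag):
    """Double-loop oracle for the cosine-normalized sliding dot product."""
    d = np.asarray(d, float)
    e = np.asarray(e, float)
    norm = np.linalg.norm(d) * np.linalg.norm(e)
    out = {}
    n = len(d)
    for lag in range(-max_lag, max_lag + 1):
        acc = 0.0
        for j in range(n):
            if 0 <= j + lag < n:
                acc += d[j] * e[j + lag]
        out[lag] = acc / norm
    return out


def _profile(peaks, kind="digital", size_range=(50, 500)):
    total = sum(a for _, a in peaks)
    peaks = [(s, 100.0 * a / total) for s, a in sorted(peaks)]
    return TRFLPProfile("s", kind, peaks, size_range)


class TestProfileToVector:
    def test_boundary_placement(self):
        profile = _profile([(50, 60.0), (500, 40.0)])
        vec = profile_to_vector(profile)
        assert len(vec) == 451
        assert vec[0] == pytest.approx(60.0)
        assert vec[-1] == pytest.approx(40.0)

    def test_renormalizes_after_window_cut(self):
        # a peak below 50 bp is outside the electropherogram window
        profile = TRFLPProfile("s", "digital", [(49, 50.0), (100, 50.0)], (1, 500))
        vec = profile_to_vector(profile, (50, 500))
        assert vec.sum() == pytest.approx(100.0)
        assert vec[50] == pytest.approx(100.0)

    def test_empty_window_is_an_error(self):
        profile = TRFLPProfile("s", "digital", [(30, 100.0)], (1, 500))
        with pytest.raises(ValueError):
            profile_to_vector(profile, (50, 500))


class TestCrossCorrelate:
    def test_identical_vectors_peak_at_zero_lag(self, rng):
        v = rng.random(451)
        result = cross_correlate(v, v)
        assert result.optimal_lag == 0
        assert result.max_coefficient == pytest.approx(1.0)

    def test_translation_recovers_lag(self):
        d = np.zeros(451)
        d[[100, 150, 230]] = [50, 30, 20]
        e = np.zeros(451)
        e[[95, 145, 225]] = [50, 30, 20]  # every peak 5 bins lower
        result = cross_correlate(d, e)
        assert result.optimal_lag == -5
        assert result.max_coefficient == pytest.approx(1.0)

    def test_disjoint_support_beyond_max_lag(self):
        d = np.zeros(451)
        e = np.zeros(451)
        d[10] = 100
        e[400] = 100
        result = cross_correlate(d, e, max_lag=20)
        assert all(c == 0 for c in result.coefficients)

    def test_zero_norm_vector_rejected(self):
        with pytest.raises(ValueError):
            cross_correlate(np.zeros(451), np.ones(451))

    def test_tie_prefers_smallest_then_negative_lag(self):
        # single-peak profiles correlate identically at many lags (all zero
        # except one): construct an exact two-way tie at +2 and -2
        d = np.zeros(51)
        e = np.zeros(51)
        d[25] = 1.0
        e[23] = 1.0
        e[27] = 1.0
        result = cross_correlate(d, e, max_lag=5)
        assert result.optimal_lag == -2

    def test_matches_brute_force_on_random_sparse_vectors(self, rng):
        for _ in range(100):
            d = np.zeros(120)
            e = np.zeros(120)
            d[rng.choice(120, size=6, replace=False)] = rng.random(6) * 50 + 1
            e[rng.choice(120, size=6, replace=False)] = rng.random(6) * 50 + 1
            result = cross_correlate(d, e, max_lag=15)
            oracle = brute_force_xcorr(d, e, 15)
            for lag, coef in zip(result.lags, result.coefficients):
                assert coef == pytest.approx(oracle[lag], abs=1e-12)

    def test_shift_recovery_property(self, rng):
        # support kept >= 10 bins from either edge so no peak leaves the
        # window under any tested shift (a noiseless translation)
        base = np.zeros(451)
        base[rng.choice(np.arange(20, 431), size=12, replace=False)] = (
            rng.random(12) * 20 + 1
        )
        for k in range(-10, 11):
            shifted = np.zeros(451)
            for i, v in enumerate(base):
                if v:
                    shifted[i + k] = v
            result = cross_correlate(base, shifted)
            assert result.optimal_lag == k
            assert result.max_coefficient == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        positions=st.lists(
            st.integers(15, 105), min_size=1, max_size=8, unique=True
        ),
        heights=st.lists(
            st.floats(0.5, 60.0, allow_nan=False), min_size=8, max_size=8
        ),
        k=st.integers(-10, 10),
    )
    def test_translation_recovery_hypothesis(self, positions, heights, k):
        base = np.zeros(121)
        for pos, h in zip(positions, heights):
            base[pos] = h
        shifted = np.zeros(121)
        for pos, h in zip(positions, heights):
            shifted[pos + k] = h
        result = cross_correlate(base, shifted, max_lag=10)
        assert result.optimal_lag == k
        assert result.max_coefficient == pytest.approx(1.0)

    def test_coefficients_bounded_for_nonnegative_vectors(self, rng):
        d = rng.random(451) * 10
        e = rng.random(451) * 10
        result = cross_correlate(d, e)
        assert all(0 <= c <= 1 + 1e-12 for c in result.coefficients)


class TestApplyShift:
    def test_negative_lag_shifts_sizes_down(self):
        profile = _profile([(219, 99.6), (150, 0.4)])
        shifted = apply_shift(profile, -5)
        assert 214 in shifted.abundances
        assert 145 in shifted.abundances

    def test_zero_lag_is_identity(self):
        profile = _profile([(100, 40.0), (200, 60.0)])
        shifted = apply_shift(profile, 0)
        assert shifted.peaks == profile.peaks

    def test_peaks_leaving_window_dropped_and_renormalized(self):
        profile = _profile([(52, 50.0), (200, 50.0)])
        shifted = apply_shift(profile, -5)
        assert shifted.peaks == [(195, 100.0)]


class TestMatchPeaks:
    def test_identical_peak_sets_fully_affiliated(self):
        e = _profile([(100, 50.0), (200, 50.0)], kind="experimental")
        d = _profile([(100, 50.0), (200, 50.0)])
        result = match_peaks(e, d)
        assert result.percent_affiliated == pytest.approx(100.0)
        assert not result.unmatched_etrfs and not result.unmatched_dtrfs

    def test_exact_match_distance_zero(self):
        e = _profile([(214, 100.0)], kind="experimental")
        d = _profile([(214, 100.0)])
        (m,) = match_peaks(e, d).matches
        assert (m.etrf_size, m.shifted_dtrf_size, m.distance) == (214, 214, 0)

    def test_beyond_tolerance_unmatched(self):
        e = _profile([(300, 100.0)], kind="experimental")
        d = _profile([(302, 100.0)])
        result = match_peaks(e, d, tolerance=1)
        assert result.matches == []
        assert result.unmatched_etrfs == [300]
        assert result.unmatched_dtrfs == [302]

    def test_each_peak_used_once_tie_prefers_smaller_dtrf(self):
        e = _profile([(200, 100.0)], kind="experimental")
        d = _profile([(199, 50.0), (201, 50.0)])
        result = match_peaks(e, d, tolerance=1)
        (m,) = result.matches
        assert m.shifted_dtrf_size == 199
        assert result.unmatched_dtrfs == [201]


class TestMirrorData:
    def test_clip_keeps_true_value(self):
        e = _profile([(100, 12.0), (200, 88.0)], kind="experimental")
        d = _profile([(100, 3.0), (200, 97.0)])
        table = mirror_data(e, d, clip=5.0)
        row = table[table.size_bp == 100].iloc[0]
        assert row.etrf_display == pytest.approx(5.0)
        assert row.etrf_abundance == pytest.approx(12.0)
        assert row.dtrf_display == pytest.approx(3.0)

    def test_table_spans_window_even_without_overlap(self):
        e = _profile([(60, 100.0)], kind="experimental")
        d = _profile([(400, 100.0)])
        table = mirror_data(e, d)
        assert table.size_bp.iloc[0] == 50
        assert table.size_bp.iloc[-1] == 500
        assert len(table) == 451

    def test_symmetric_profiles_give_symmetric_columns(self):
        e = _profile([(100, 30.0), (200, 70.0)], kind="experimental")
        table = mirror_data(e, e)
        assert (table.etrf_abundance == table.dtrf_abundance).all()
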