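"""Window selection, spectral-centroid frequency, maps, profiles, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletpulse import (FrequencyMapper, FrequencyProfile, GradientMap,
                        RatioStack, cog_frequency, frequency_map,
                        make_oxygen_gradient, peak_frequency,
                        profile_vs_position, select_analysis_window)
from conftest import naive_dft_cog

TIMES46 = np.arange(46.0)  # 0..45 min at 1-min intervals


class TestSelectAnalysisWindow:
    def test_reference_timeline_with_overshoot_dropped(self):
        w = select_analysis_window(TIMES46, 12, 36, drop_first=True)
        assert len(w) == 24
        assert w.times[0] == 13.0 and w.times[-1] == 36.0

    def test_reference_timeline_without_drop(self):
        w = select_analysis_window(TIMES46, 12, 36, drop_first=False)
        assert len(w) == 25
        assert w.times[0] == 12.0 and w.times[-1] == 36.0

    def test_window_outside_timeline_rejected(self):
        with pytest.raises(ValueError):
            select_analysis_window(TIMES46, 100, 120)

    def test_nonuniform_times_rejected(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="uniform"):
            select_analysis_window(t, 0, 5)


def cosine_series(cycles, n=24, dt=1.0):
    m = np.arange(n)
    return np.cos(2 * np.pi * cycles * m / n)


class TestCogFrequency:
    def test_all_zero_series_gives_zero(self):
        assert cog_frequency(np.zeros(24), 1.0) == 0.0
        assert cog_frequency(np.zeros(9), 1.0) == 0.0

    def test_exact_bin_cosine(self):
        # 4 cycles over 24 one-minute samples: all magnitude in bin k=4
        assert cog_frequency(cosine_series(4), 1.0) == pytest.approx(10.0)

    def test_interior_impulse_flat_spectrum(self):
        # flat magnitudes => arithmetic mean of bins 1..12 = 6.5/24 per min
        v = np.zeros(24)
        v[7] = 1.0
        assert cog_frequency(v, 1.0) == pytest.approx(16.25)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(8, 65))
            v = rng.normal(size=n)
            dt = float(rng.uniform(0.25, 2.0))
            assert cog_frequency(v, dt) == pytest.approx(
                naive_dft_cog(v, dt), rel=1e-9)

    @given(st.floats(-100, 100).filter(lambda c: abs(c) > 1e-6),
           st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, c, seed):
        v = np.random.default_rng(seed).normal(size=16)
        assert cog_frequency(c * v, 1.0) == pytest.approx(
            cog_frequency(v, 1.0), rel=1e-9)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(4, 48))
    @settings(deadline=None, max_examples=50)
    def test_range_within_nyquist(self, seed, n):
        v = np.random.default_rng(seed).normal(size=n)
        f = cog_frequency(v, 1.0)
        assert 0.0 <= f <= 60.0 / 2.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cog_frequency(np.ones(3), 1.0)


def _ratio_stack_from(values):
    T = values.shape[0]
    return RatioStack(values=values, times=np.arange(float(T)),
                      mask=np.ones(values.shape[1:], dtype=bool))


class TestFrequencyMap:
    def test_uniform_cosine_stack_gives_constant_map(self):
        v = np.tile(cosine_series(4)[:, None, None], (1, 3, 5))
        rs = _ratio_stack_from(v)
        w = select_analysis_window(rs.times, 0, 23)
        fmap = frequency_map(rs, w, detrend=False)
        np.testing.assert_allclose(fmap.values, 10.0, rtol=1e-9)

    def test_two_region_stack_is_local(self):
        left = cosine_series(4)   # 10 per hour
        right = cosine_series(6)  # 15 per hour
        v = np.empty((24, 2, 8))
        v[:, :, :4] = left[:, None, None]
        v[:, :, 4:] = right[:, None, None]
        rs = _ratio_stack_from(v)
        fmap = frequency_map(rs, select_analysis_window(rs.times, 0, 23),
                             detrend=False)
        np.testing.assert_allclose(fmap.values[:, :4], 10.0, rtol=1e-9)
        np.testing.assert_allclose(fmap.values[:, 4:], 15.0, rtol=1e-9)

    def test_default_synthetic_within_nyquist(self, default_ratio_stack):
        w = select_analysis_window(default_ratio_stack.times, 12, 36, True)
        fmap = frequency_map(default_ratio_stack, w)
        vals = fmap.values[fmap.mask]
        assert np.all((vals >= 0) & (vals <= 30.0))

    def test_masked_pixels_stay_masked(self):
        v = np.tile(cosine_series(4)[:, None, None], (1, 2, 2))
        rs = RatioStack(values=v, times=np.arange(24.0),
                        mask=np.array([[True, False], [True, True]]))
        fmap = frequency_map(rs, select_analysis_window(rs.times, 0, 23))
        assert np.isnan(fmap.values[0, 1])
        assert not fmap.mask[0, 1]

    def test_block_processing_matches_whole_image(self, default_ratio_stack):
        w = select_analysis_window(default_ratio_stack.times, 12, 36, True)
        whole = frequency_map(default_ratio_stack, w)
        blocked = frequency_map(default_ratio_stack, w, block_height=17)
        np.testing.assert_allclose(blocked.values, whole.values, rtol=1e-12)

    def test_window_beyond_stack_rejected(self, default_ratio_stack):
        w = select_analysis_window(np.arange(100.0), 50, 90)
        with pytest.raises(ValueError):
            frequency_map(default_ratio_stack, w)

    def test_display_normalization_spans_unit_interval(self, default_ratio_stack):
        w = select_analysis_window(default_ratio_stack.times, 12, 36, True)
        norm = frequency_map(default_ratio_stack, w).normalized()
        assert np.nanmin(norm) == 0.0 and np.nanmax(norm) == 1.0


class TestFrequencyMapperEstimator:
    def test_sklearn_params_round_trip(self):
        m = FrequencyMapper(stim_start=5.0, drop_first=False)
        params = m.get_params()
        assert params["stim_start"] == 5.0
        m2 = FrequencyMapper().set_params(**params)
        assert m2.get_params() == params

    def test_fit_learns_stimulation_window(self, default_ratio_stack):
        m = FrequencyMapper().fit(default_ratio_stack)
        assert m.n_frames_ == 24

    def test_transform_before_fit_rejected(self, default_ratio_stack):
        with pytest.raises(RuntimeError):
            FrequencyMapper().transform(default_ratio_stack)


class TestProfileAndPeak:
    def _map(self, values, mask=None):
        from isletpulse.fourier import FrequencyMap
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        return FrequencyMap(values=values, mask=mask, dt=1.0)

    def test_constant_map_gives_constant_profile(self):
        prof = profile_vs_position(self._map(np.full((4, 6), 7.0)))
        np.testing.assert_allclose(prof.freq_per_hr, 7.0)

    def test_single_row_profile_equals_row(self):
        row = np.array([[1.0, 2.0, 3.0]])
        prof = profile_vs_position(self._map(row))
        np.testing.assert_allclose(prof.freq_per_hr, row[0])

    def test_column_mean(self):
        prof = profile_vs_position(self._map(np.array([[8.0], [12.0]])))
        assert prof.freq_per_hr[0] == pytest.approx(10.0)

    def test_fully_masked_column_flagged(self):
        vals = np.full((2, 3), 5.0)
        mask = np.ones((2, 3), dtype=bool)
        mask[:, 1] = False
        prof = profile_vs_position(self._map(vals, mask))
        assert np.isnan(prof.freq_per_hr[1])
        assert not prof.valid[1]

    def test_unique_peak_at_12_percent(self):
        grad = make_oxygen_gradient(11, 20.0, "half")  # o2 = 0,2,...,20
        f = np.full(11, 6.0)
        f[6] = 13.5  # column mapped to 12% O2
        pk = peak_frequency(FrequencyProfile(freq_per_hr=f,
                                             columns=np.arange(11)), grad)
        assert pk.o2_percent == pytest.approx(12.0)
        assert pk.freq_per_hr == pytest.approx(13.5)
        assert pk.period_min == pytest.approx(60 / 13.5)  # 4.44 -> "4.4/cycle"
        assert round(pk.period_min, 1) == 4.4
        assert pk.unique

    def test_constant_profile_ties_to_lowest_o2(self):
        grad = make_oxygen_gradient(11, 20.0, "half")
        pk = peak_frequency(FrequencyProfile(freq_per_hr=np.full(11, 9.0),
                                             columns=np.arange(11)), grad)
        assert pk.column == 0 and pk.o2_percent == 0.0
        assert not pk.unique

    def test_symmetric_full_gradient_resolves_to_lower_index(self):
        grad = make_oxygen_gradient(11, 20.0, "full")
        f = np.array([1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1.0])
        f[2] = f[8] = 9.0  # mirrored twin peaks
        pk = peak_frequency(FrequencyProfile(freq_per_hr=f,
                                             columns=np.arange(11)), grad)
        assert pk.column == 2
        assert pk.o2_percent == pytest.approx(grad.o2[8])  # same O2 by symmetry

    def test_all_masked_profile_rejected(self):
        grad = make_oxygen_gradient(3, 20.0, "half")
        with pytest.raises(ValueError):
            peak_frequency(FrequencyProfile(freq_per_hr=np.full(3, np.nan),
                                            columns=np.arange(3)), grad)

    def test_smoothing_moves_peak_off_a_spike(self):
        grad = make_oxygen_gradient(9, 20.0, "half")
        f = np.array([1, 1, 8, 1, 5, 6, 5, 1, 1.0])  # narrow spike vs broad bump
        raw = peak_frequency(FrequencyProfile(freq_per_hr=f,
                                              columns=np.arange(9)), grad)
        smoothed = peak_frequency(FrequencyProfile(freq_per_hr=f,
                                                   columns=np.arange(9)),
                                  grad, smooth_width=3)
        assert raw.column == 2
        assert smoothed.column == 5
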