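"""Peak detection, period, lag statistics and phenotype classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luxlink.analysis import (
    PeakList,
    classify_response,
    detect_peaks,
    estimate_period,
    first_peak_ratio,
    peak_lags,
    resample,
)
from luxlink.errors import (
    InputDomainError,
    InsufficientPeaksError,
    NoMatchError,
    ResamplingError,
)
from luxlink.traces import TraceSet


def _trace(times, values, name="F_sender"):
    return TraceSet(np.asarray(times, float), {name: np.asarray(values, float)})


class TestResample:
    def test_exact_grid_hit(self):
        t = np.arange(0.0, 31.0)
        tr = _trace(t, t ** 2)
        out = resample(tr, 3.0)
        np.testing.assert_allclose(out.times, np.arange(0.0, 31.0, 3.0))
        np.testing.assert_allclose(out.channel("F_sender"),
                                   np.arange(0.0, 31.0, 3.0) ** 2)

    def test_constant_stays_constant(self):
        tr = _trace(np.arange(0.0, 100.0), np.full(100, 7.5))
        out = resample(tr, 6.0)
        assert np.all(out.channel("F_sender") == 7.5)

    def test_linear_interpolation_exact(self):
        tr = _trace(np.arange(0.0, 11.0), np.arange(0.0, 11.0))
        out = resample(tr, 4.0)
        np.testing.assert_allclose(out.times, [0.0, 4.0, 8.0])
        np.testing.assert_allclose(out.channel("F_sender"), [0.0, 4.0, 8.0])

    def test_upsampling_rejected(self):
        tr = _trace(np.arange(0.0, 10.0, 2.0), np.zeros(5))
        with pytest.raises(ResamplingError):
            resample(tr, 1.0)


class TestDetectPeaks:
    def test_sine_peaks_at_maxima(self, sine_trace):
        pk = detect_peaks(sine_trace.times, sine_trace.channel("F_sender"))
        np.testing.assert_allclose(pk.times, [15.0, 75.0, 135.0])

    def test_constant_channel_has_no_peaks(self):
        pk = detect_peaks(np.arange(10.0), np.full(10, 7.0))
        assert len(pk) == 0

    def test_single_triangular_pulse(self):
        t = np.arange(0.0, 61.0)
        v = np.maximum(0.0, 10.0 - np.abs(t - 30.0))
        pk = detect_peaks(t, v)
        assert list(pk.times) == [30.0]

    def test_separation_keeps_higher_peak(self):
        t = np.arange(0.0, 40.0)
        v = np.zeros_like(t)
        v[10] = 5.0
        v[18] = 8.0  # within 15 min of the first; higher wins
        pk = detect_peaks(t, v, min_separation=15.0)
        assert list(pk.times) == [18.0]

    def test_amplitude_scale_invariance(self, sine_trace):
        t = sine_trace.times
        v = sine_trace.channel("F_sender")
        a = detect_peaks(t, v)
        b = detect_peaks(t, 137.0 * v)
        np.testing.assert_allclose(a.times, b.times)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputDomainError):
            detect_peaks(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestEstimatePeriod:
    def test_equal_spacing(self):
        assert estimate_period(PeakList([15.0, 75.0, 135.0], [1, 1, 1])) == 60.0

    def test_median_of_intervals(self):
        pk = PeakList([10.0, 70.0, 131.0, 190.0], [1, 1, 1, 1])
        assert estimate_period(pk) == 60.0  # median of {60, 61, 59}

    def test_insufficient_peaks(self):
        with pytest.raises(InsufficientPeaksError):
            estimate_period(PeakList([0.0, 50.0], [1, 1]))


class TestPeakLags:
    def test_identity_gives_zero_lag(self):
        s = PeakList([15.0, 75.0, 135.0], [1, 1, 1])
        stats = peak_lags(s, s, exclude_first_receiver=False)
        assert stats.median_abs_lag == 0.0
        assert stats.n_matched == 3

    def test_uniform_shift(self):
        s = PeakList([15.0, 75.0, 135.0], [1, 1, 1])
        r = PeakList([18.0, 78.0, 138.0], [1, 1, 1])
        stats = peak_lags(s, r, exclude_first_receiver=False)
        np.testing.assert_allclose(stats.lags, [3.0, 3.0, 3.0])
        assert stats.median_abs_lag == 3.0

    def test_unmatched_receiver_peak_counted(self):
        s = PeakList([15.0, 75.0, 135.0], [1, 1, 1])
        r = PeakList([15.0, 75.0, 135.0, 300.0], [1, 1, 1, 1])
        stats = peak_lags(s, r, max_window=30.0, exclude_first_receiver=False)
        assert stats.n_matched == 3
        assert stats.n_unmatched_receiver == 1

    def test_first_receiver_peak_excluded_by_default(self):
        s = PeakList([15.0, 75.0, 135.0], [1, 1, 1])
        r = PeakList([10.0, 75.0, 135.0], [9, 1, 1])
        stats = peak_lags(s, r)
        assert stats.n_matched == 2
        assert stats.median_abs_lag == 0.0

    def test_no_match_raises(self):
        s = PeakList([0.0, 60.0, 120.0], [1, 1, 1])
        r = PeakList([500.0, 600.0], [1, 1])
        with pytest.raises(NoMatchError):
            peak_lags(s, r, max_window=10.0, exclude_first_receiver=False)


class TestFirstPeakRatio:
    @pytest.mark.parametrize(
        ("amps", "expected"),
        [([100.0, 50.0, 55.0, 48.0], 2.0),
         ([50.0, 50.0, 50.0], 1.0),
         ([10.0, 50.0, 55.0], 10.0 / 52.5)],
    )
    def test_values(self, amps, expected):
        pk = PeakList(np.arange(len(amps)) * 60.0, amps)
        assert first_peak_ratio(pk) == pytest.approx(expected, abs=1e-9)

    def test_needs_three_peaks(self):
        with pytest.raises(InsufficientPeaksError):
            first_peak_ratio(PeakList([0.0, 60.0], [1.0, 1.0]))


class TestClassifyResponse:
    def test_constant_at_basal_is_silent(self):
        t = np.arange(0.0, 100.0, 3.0)
        call = classify_response(t, np.full_like(t, 1.0), basal=1.0)
        assert call.label == "silent"

    def test_sine_is_oscillatory(self):
        t = np.arange(0.0, 400.0, 3.0)
        v = 50.0 + 40.0 * np.sin(2.0 * np.pi * t / 60.0)
        call = classify_response(t, v, basal=1.0)
        assert call.label == "oscillatory"
        assert call.evidence["peak_count"] >= 3

    def test_saturating_ramp_is_accumulating(self):
        t = np.arange(0.0, 600.0, 3.0)
        v = 100.0 / (1.0 + np.exp(-(t - 200.0) / 40.0))
        call = classify_response(t, v, basal=1.0)
        assert call.label == "accumulating"

    def test_suppressed_vs_reference(self):
        t = np.arange(0.0, 400.0, 3.0)
        v = np.full_like(t, 3.0) + 0.5 * np.sin(t / 10.0)
        call = classify_response(t, v, basal=1.0, reference_peak=100.0)
        assert call.label == "suppressed"

    def test_silent_takes_precedence_over_suppressed(self):
        t = np.arange(0.0, 100.0, 3.0)
        call = classify_response(t, np.full_like(t, 1.0), basal=1.0,
                                 reference_peak=1000.0)
        assert call.label == "silent"


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(min_value=0.0, max_value=500.0),
           scale=st.floats(min_value=0.01, max_value=100.0))
    def test_shift_and_scale_equivariance(self, shift, scale):
        """Time shifts move peak times; amplitude scaling changes nothing."""
        t = np.arange(0.0, 400.0, 3.0)
        v = 50.0 + 40.0 * np.sin(2.0 * np.pi * t / 60.0)
        ref = detect_peaks(t, v)
        moved = detect_peaks(t + shift, scale * v)
        np.testing.assert_allclose(moved.times, ref.times + shift, atol=1e-9)
        assert estimate_period(moved) == pytest.approx(estimate_period(ref))
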