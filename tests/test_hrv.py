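"""HRV chain: filtering, resampling, band power, segment means, peak detection."""

import numpy as np
import pytest

from simstress.hrv import (
    FilterSpec,
    RRSeries,
    UniformSeries,
    band_power_track,
    butterworth_filter,
    detect_r_peaks,
    median_filter_rr,
    repair_ectopics,
    resample_rr,
    segment_mean_ratio,
)
from simstress.io import read_rr_csv, write_rr_csv
from simstress.synth import RRModulationSpec, generate_rr, inject_ectopics, make_ecg


def _sinusoid(freq, amp=1.0, rate=4.0, duration=600.0):
    t = np.arange(int(duration * rate)) / rate
    return UniformSeries(0.0, rate, amp * np.sin(2 * np.pi * freq * t))


class TestMedianFilter:
    def test_hand_computed_medians_with_replicate_padding(self):
        rr = RRSeries.from_intervals([800, 810, 1600, 805, 795])
        out = median_filter_rr(rr, kernel=3)
        assert np.array_equal(out.intervals, [800, 810, 810, 805, 795])

    def test_constant_series_unchanged(self, constant_rr):
        out = median_filter_rr(constant_rr, kernel=5)
        assert np.array_equal(out.intervals, constant_rr.intervals)

    def test_beat_times_rebuilt_from_first_beat(self):
        rr = RRSeries.from_intervals([800, 810, 1600, 805, 795], t0=10.0)
        out = median_filter_rr(rr, kernel=3)
        assert out.beat_times[0] == 10.0
        assert out.beat_times[-1] == pytest.approx(10.0 + out.intervals.sum() / 1000)

    def test_even_kernel_rejected(self, constant_rr):
        with pytest.raises(ValueError, match="odd"):
            median_filter_rr(constant_rr, kernel=4)

    def test_short_series_rejected(self):
        rr = RRSeries.from_intervals([800, 805, 810])
        with pytest.raises(ValueError, match="fewer"):
            median_filter_rr(rr, kernel=5)


class TestRepairEctopics:
    def test_identity_on_clean_modulated_series(self, lf_modulated_rr):
        series, _ = lf_modulated_rr
        out = repair_ectopics(series, kernel=5, threshold=0.2)
        assert np.array_equal(out.intervals, series.intervals)

    def test_repairs_injected_couplets(self, constant_rr):
        corrupted, idx = inject_ectopics(constant_rr, rate=0.03, magnitude=0.5, seed=2)
        repaired = repair_ectopics(corrupted, kernel=5, threshold=0.2)
        assert np.allclose(repaired.intervals[idx], 800.0, rtol=0.05)
        assert np.allclose(repaired.intervals[idx + 1], 800.0, rtol=0.05)


class TestResample:
    def test_constant_series_resamples_to_constant(self, constant_rr):
        out = resample_rr(constant_rr, rate=4.0)
        assert np.allclose(out.values, 800.0)
        assert out.rate == 4.0

    def test_spline_passes_through_knots(self):
        # quarter-second intervals put every knot exactly on the 4 Hz grid
        rr = RRSeries.from_intervals([250.0] * 40)
        out = resample_rr(rr, rate=4.0)
        knot_idx = np.rint((rr.beat_times[:-1] - out.start_time) * 4.0).astype(int)
        assert np.allclose(out.values[knot_idx], rr.intervals, atol=1e-9)

    def test_sinusoidal_amplitude_preserved_within_2pct(self):
        spec = RRModulationSpec(amp_lf=30.0, freq_lf=0.1, duration=300.0, seed=0)
        series, _ = generate_rr(spec)
        out = resample_rr(series, rate=4.0)
        interior = out.values[100:-100] - 800.0
        amp = (interior.max() - interior.min()) / 2
        assert amp == pytest.approx(30.0, rel=0.02)

    def test_too_few_beats_rejected(self):
        rr = RRSeries.from_intervals([800, 800, 800])
        with pytest.raises(ValueError, match="at least 4"):
            resample_rr(rr)


class TestButterworth:
    def test_passband_sinusoid_preserved(self):
        series = _sinusoid(0.25)
        out = butterworth_filter(series, FilterSpec(0.04, 0.4))
        interior = out.values[400:-400]
        assert np.abs(interior).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_sinusoid_attenuated_20db(self):
        series = _sinusoid(0.01)
        out = butterworth_filter(series, FilterSpec(0.04, 0.4))
        interior = out.values[400:-400]
        assert np.abs(interior).max() < 0.1

    def test_zero_input_zero_output(self):
        series = UniformSeries(0.0, 4.0, np.zeros(1000))
        out = butterworth_filter(series, FilterSpec(0.04, 0.4))
        assert np.allclose(out.values, 0.0)

    def test_band_edge_at_nyquist_rejected(self):
        series = _sinusoid(0.25)
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_filter(series, FilterSpec(0.04, 2.0))


class TestBandPowerTrack:
    def test_pure_lf_sinusoid_recovers_analytic_power(self):
        series = _sinusoid(0.095, amp=30.0, duration=600.0)
        track = band_power_track(series)
        assert np.allclose(track.lf_power, 450.0, rtol=0.1)
        assert np.all(track.hf_power < 0.05 * track.lf_power)

    def test_homogeneity_scaling(self):
        series = _sinusoid(0.095, amp=30.0, duration=600.0)
        doubled = UniformSeries(0.0, 4.0, 2.0 * series.values)
        t1 = band_power_track(series)
        t2 = band_power_track(doubled)
        assert np.allclose(t2.lf_power, 4.0 * t1.lf_power, rtol=1e-6)
        assert np.allclose(t2.ratio, t1.ratio, rtol=1e-6, equal_nan=True)

    def test_band_separation_oracle(self):
        for freq, band in [(0.095, "lf"), (0.25, "hf")]:
            track = band_power_track(_sinusoid(freq, amp=10.0, duration=600.0))
            in_band = track.lf_power if band == "lf" else track.hf_power
            out_band = track.hf_power if band == "lf" else track.lf_power
            total = in_band + out_band
            assert np.all(in_band / total >= 0.95)

    def test_equal_amplitude_bands_give_unit_ratio(self):
        spec = RRModulationSpec(amp_lf=30, amp_hf=30, duration=300, seed=0)
        series, _ = generate_rr(spec)
        track = band_power_track(resample_rr(series))
        assert np.allclose(track.ratio, 1.0, rtol=0.15)

    def test_window_longer_than_series_rejected(self):
        series = _sinusoid(0.095, duration=40.0)
        with pytest.raises(ValueError, match="longer"):
            band_power_track(series, window=60.0)


class TestSegmentMeanRatio:
    @staticmethod
    def _track(centers, ratios):
        from simstress.hrv import BandPowerTrack

        arr = np.asarray(ratios, dtype=float)
        return BandPowerTrack(
            np.asarray(centers, dtype=float), arr, np.ones_like(arr), arr,
            window_length=60.0, hop=30.0,
        )

    def test_constant_ratio(self):
        result = segment_mean_ratio(self._track([10, 20, 30], [2, 2, 2]), (0, 40))
        assert result.mean == 2.0 and result.sd == 0.0 and result.n_windows == 3

    def test_hand_computed_mean_and_sd(self):
        result = segment_mean_ratio(self._track([10, 20], [1, 3]), (0, 30))
        assert result.mean == pytest.approx(2.0)
        assert result.sd == pytest.approx(np.sqrt(2.0))

    def test_half_open_interval_excludes_end(self):
        result = segment_mean_ratio(self._track([10, 20], [1, 3]), (0, 20))
        assert result.n_windows == 1 and result.mean == 1.0

    def test_empty_segment_names_the_segment(self):
        with pytest.raises(ValueError, match="warmup"):
            segment_mean_ratio(self._track([10], [2]), (100, 200), segment="warmup")


class TestDetectRPeaks:
    def test_regular_spikes_recovered_within_one_sample(self, constant_rr):
        ecg = make_ecg(constant_rr, fs=250.0, noise_sd=0.01, seed=0)
        beats = detect_r_peaks(ecg)
        intervals = np.diff(beats) * 1000
        assert np.all(np.abs(intervals - 800.0) <= 4.0)

    def test_refractory_suppresses_close_spike(self):
        fs = 250.0
        t = np.arange(int(5 * fs)) / fs
        x = np.zeros_like(t)
        for spike in (1.0, 1.1, 2.0):
            x += np.exp(-0.5 * ((t - spike) / 0.01) ** 2)
        from simstress.hrv import EcgTrace

        beats = detect_r_peaks(EcgTrace(t, x, fs), refractory=0.3)
        assert len(beats) == 2

    def test_flat_trace_warns_and_returns_empty(self):
        from simstress.hrv import EcgTrace

        fs = 250.0
        t = np.arange(int(3 * fs)) / fs
        with pytest.warns(UserWarning, match="flat"):
            beats = detect_r_peaks(EcgTrace(t, np.zeros_like(t), fs))
        assert beats.size == 0

    def test_round_trip_from_generated_series(self, lf_modulated_rr):
        series, _ = lf_modulated_rr
        # offset so the first R complex is not clipped at the grid edge
        short = RRSeries.from_beat_times(series.beat_times[:40] + 1.0)
        ecg = make_ecg(short, fs=250.0, noise_sd=0.0)
        beats = detect_r_peaks(ecg)
        assert beats.size == short.n_beats
        assert np.all(np.abs(np.diff(beats) * 1000 - short.intervals) <= 4.0)


class TestEndToEnd:
    def test_identical_csv_gives_bit_identical_track(self, tmp_path, lf_modulated_rr):
        series, _ = lf_modulated_rr
        path = tmp_path / "rr.csv"
        write_rr_csv(series, path)
        tracks = []
        for _ in range(2):
            loaded = read_rr_csv(path)
            tracks.append(band_power_track(resample_rr(loaded)))
        assert np.array_equal(tracks[0].lf_power, tracks[1].lf_power)
        assert np.array_equal(tracks[0].hf_power, tracks[1].hf_power)
        assert np.array_equal(tracks[0].ratio, tracks[1].ratio)

    def test_parameter_recovery_through_full_chain(self):
        spec = RRModulationSpec(amp_lf=40, amp_hf=20, duration=300, seed=3)
        series, truth = generate_rr(spec)
        track = band_power_track(resample_rr(series))
        result = segment_mean_ratio(track, (0.0, 1e9))
        expected = truth["lf_power_ms2"] / truth["hf_power_ms2"]
        assert 0.85 * expected <= result.mean <= 1.15 * expected
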