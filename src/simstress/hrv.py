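"""Beat-to-beat interval processing and frequency-domain heart-rate variability.

The analysis chain follows the standard filter-based frequency-domain HRV
recipe for short recordings:

1. clean the RR (inter-beat interval) sequence with a median filter, which
   removes the short/long couplets left by ectopic beats;
2. resample the irregularly spaced tachogram onto a uniform 4 Hz grid by
   cubic-spline interpolation;
3. split the tachogram into its low-frequency (LF, 0.04-0.15 Hz) and
   high-frequency (HF, 0.15-0.4 Hz) components with zero-phase 4th-order
   Butterworth band-pass filters;
4. track band power (mean squared amplitude of each component) over
   overlapping windows, and summarise the LF/HF power ratio per study
   segment.

HF power is dominated by respiratory sinus arrhythmia and indexes
parasympathetic activity; LF power mixes sympathetic and baroreflex
influences.  Their ratio is widely used as an index of sympatho-vagal
balance: it rises under mental effort and pre-performance stress.

All times are seconds from recording start; intervals are milliseconds;
band powers are ms^2 and ratios dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter as _nd_median_filter

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "RR_PLAUSIBLE_MS",
    "RRSeries",
    "UniformSeries",
    "FilterSpec",
    "BandPowerTrack",
    "SegmentRatio",
    "EcgTrace",
    "detect_r_peaks",
    "median_filter_rr",
    "repair_ectopics",
    "resample_rr",
    "butterworth_filter",
    "band_power_track",
    "segment_mean_ratio",
]

#: Canonical short-term HRV frequency bands (Hz).
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Physiologically plausible RR interval range (ms); values outside are
#: flagged with a warning but not deleted (artifact removal is the median
#: filter's job).
RR_PLAUSIBLE_MS = (200.0, 3000.0)

_EPS = 1e-9


@dataclass
class RRSeries:
    """A sequence of heartbeats: beat occurrence times and RR intervals.

    ``beat_times`` holds N+1 strictly increasing times in seconds;
    ``intervals`` holds the N inter-beat intervals in milliseconds, with
    ``intervals[i] == (beat_times[i+1] - beat_times[i]) * 1000``.  The
    tachogram knot convention pairs ``intervals[i]`` with its *starting*
    beat time ``beat_times[i]``.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    participant_id: str | None = None
    segment: str | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.beat_times.ndim != 1 or self.intervals.ndim != 1:
            raise ValueError("beat_times and intervals must be 1-D")
        if self.beat_times.size != self.intervals.size + 1:
            raise ValueError(
                f"expected len(beat_times) == len(intervals) + 1, got "
                f"{self.beat_times.size} and {self.intervals.size}"
            )
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        implied = np.diff(self.beat_times) * 1000.0
        if not np.allclose(implied, self.intervals, rtol=1e-9, atol=1e-3):
            raise ValueError("intervals inconsistent with beat time differences")
        lo, hi = RR_PLAUSIBLE_MS
        n_bad = int(np.sum((self.intervals < lo) | (self.intervals > hi)))
        if n_bad:
            warnings.warn(
                f"{n_bad} RR interval(s) outside the plausible range "
                f"[{lo:.0f}, {hi:.0f}] ms; consider median filtering",
                stacklevel=2,
            )

    @classmethod
    def from_intervals(
        cls,
        intervals: np.ndarray,
        t0: float = 0.0,
        participant_id: str | None = None,
        segment: str | None = None,
    ) -> "RRSeries":
        """Build a series from intervals alone, cumulating times from ``t0``."""
        intervals = np.asarray(intervals, dtype=float)
        beat_times = t0 + np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
        return cls(beat_times, intervals, participant_id, segment)

    @classmethod
    def from_beat_times(
        cls,
        beat_times: np.ndarray,
        participant_id: str | None = None,
        segment: str | None = None,
    ) -> "RRSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        return cls(beat_times, np.diff(beat_times) * 1000.0, participant_id, segment)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def duration(self) -> float:
        """Elapsed time (s) between the first and last beat."""
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class UniformSeries:
    """An evenly sampled real-valued series (e.g. the 4 Hz tachogram)."""

    start_time: float
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.size < 2:
            raise ValueError("a uniform series needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.values.size - 1) / self.rate


@dataclass(frozen=True)
class FilterSpec:
    """A band-pass Butterworth filter specification."""

    low: float
    high: float
    order: int = 4
    zero_phase: bool = True
    kind: str = "bandpass"

    def validate(self, rate: float) -> None:
        if self.kind != "bandpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")
        if self.high >= rate / 2:
            raise ValueError(
                f"band edge {self.high} Hz is at or above Nyquist ({rate / 2} Hz)"
            )


@dataclass
class BandPowerTrack:
    """Windowed LF power, HF power and their ratio over time."""

    window_centers: np.ndarray
    lf_power: np.ndarray
    hf_power: np.ndarray
    ratio: np.ndarray
    window_length: float
    hop: float

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.lf_power = np.asarray(self.lf_power, dtype=float)
        self.hf_power = np.asarray(self.hf_power, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)


@dataclass(frozen=True)
class SegmentRatio:
    """Mean +/- SD of the windowed LF/HF ratio within one study segment."""

    mean: float
    sd: float
    n_windows: int
    segment: str | None = None


@dataclass
class EcgTrace:
    """A uniformly sampled single-lead ECG (nominal 250 Hz)."""

    sample_times: np.ndarray
    amplitude: np.ndarray
    rate: float = 250.0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.sample_times.size != self.amplitude.size:
            raise ValueError("sample_times and amplitude must have equal length")
        if self.sample_times.size <= 2 * self.rate:
            raise ValueError("ECG trace shorter than 2 s at the nominal rate")
        dt = np.diff(self.sample_times)
        if np.any(np.abs(dt - 1.0 / self.rate) > 0.01 / self.rate):
            raise ValueError("ECG sampling is not uniform at the declared rate")


def detect_r_peaks(ecg: EcgTrace, refractory: float = 0.3) -> np.ndarray:
    """Detect R-peak times in an ECG trace.

    Local maxima above an adaptive threshold (midway between the trace mean
    and maximum), separated by at least ``refractory`` seconds.  Returns the
    detected beat times (s).  A flat trace yields an empty result with a
    warning.
    """
    if refractory < 0.2:
        raise ValueError("refractory period must be >= 0.2 s")
    x = ecg.amplitude
    if np.ptp(x) < 1e-12:
        warnings.warn("flat ECG trace: no R peaks detected", stacklevel=2)
        return np.empty(0, dtype=float)
    threshold = x.mean() + 0.5 * (x.max() - x.mean())
    distance = max(1, int(round(refractory * ecg.rate)))
    peaks, _ = signal.find_peaks(x, height=threshold, distance=distance)
    return ecg.sample_times[peaks]


def median_filter_rr(rr: RRSeries, kernel: int = 5) -> RRSeries:
    """Median-filter the RR interval sequence in the beat domain.

    Each interval is replaced by the median of its ``kernel``-wide
    neighbourhood with replicate (nearest) padding at the edges; beat times
    are rebuilt by cumulative summation from the original first beat time.
    The filter runs *before* spline resampling so that an ectopic couplet is
    removed while it still occupies isolated samples.
    """
    if kernel % 2 == 0:
        raise ValueError("median filter kernel must be odd")
    if kernel < 3:
        raise ValueError("median filter kernel must be >= 3")
    if rr.intervals.size < kernel:
        raise ValueError(
            f"series has {rr.intervals.size} intervals, fewer than kernel {kernel}"
        )
    filtered = _nd_median_filter(rr.intervals, size=kernel, mode="nearest")
    return RRSeries.from_intervals(
        filtered, t0=float(rr.beat_times[0]),
        participant_id=rr.participant_id, segment=rr.segment,
    )


def repair_ectopics(
    rr: RRSeries, kernel: int = 5, threshold: float = 0.2
) -> RRSeries:
    """Threshold-gated median repair of ectopic intervals.

    An interval is replaced by the median of its ``kernel``-wide
    neighbourhood only when it deviates from that median by more than
    ``threshold`` (as a fraction of the median).  Unlike the plain moving
    median (:func:`median_filter_rr`), this is the identity on clean series,
    so respiratory (HF) modulation — whose period at normal heart rates spans
    only a few beats — passes through undistorted while ectopic couplets,
    which deviate by far more than any physiological modulation, are removed.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    if rr.intervals.size < kernel:
        raise ValueError(
            f"series has {rr.intervals.size} intervals, fewer than kernel {kernel}"
        )
    local_median = _nd_median_filter(rr.intervals, size=kernel, mode="nearest")
    deviant = np.abs(rr.intervals - local_median) > threshold * local_median
    repaired = np.where(deviant, local_median, rr.intervals)
    return RRSeries.from_intervals(
        repaired, t0=float(rr.beat_times[0]),
        participant_id=rr.participant_id, segment=rr.segment,
    )


def resample_rr(rr: RRSeries, rate: float = 4.0) -> UniformSeries:
    """Resample the tachogram onto a uniform grid by natural cubic spline.

    The spline passes exactly through every knot ``(beat_times[i],
    intervals[i])`` and is evaluated on a grid at ``rate`` Hz spanning the
    knot times.
    """
    if rr.intervals.size < 4:
        raise ValueError("need at least 4 intervals for cubic-spline resampling")
    knot_t = rr.beat_times[:-1]
    knot_y = rr.intervals
    if np.any(np.diff(knot_t) <= 0):
        raise ValueError("duplicate or non-increasing beat times")
    spline = CubicSpline(knot_t, knot_y, bc_type="natural")
    span = knot_t[-1] - knot_t[0]
    n_samples = int(np.floor(span * rate + _EPS)) + 1
    grid = knot_t[0] + np.arange(n_samples) / rate
    return UniformSeries(start_time=float(knot_t[0]), rate=rate, values=spline(grid))


def butterworth_filter(series: UniformSeries, spec: FilterSpec) -> UniformSeries:
    """Apply a Butterworth band-pass filter to a uniform series.

    Zero-phase mode applies the filter forward and backward (``sosfiltfilt``):
    no phase lag, attenuation doubled in dB.  Output lies on the same grid as
    the input.
    """
    spec.validate(series.rate)
    sos = signal.butter(
        spec.order, [spec.low, spec.high], btype="bandpass", output="sos",
        fs=series.rate,
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, series.values)
    else:
        filtered = signal.sosfilt(sos, series.values)
    return UniformSeries(series.start_time, series.rate, filtered)


def band_power_track(
    series: UniformSeries,
    window: float = 60.0,
    hop: float = 30.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    order: int = 4,
    zero_phase: bool = True,
    broadband_prefilter: bool = True,
    drop_transient_windows: bool = True,
) -> BandPowerTrack:
    """Windowed LF/HF band power of a uniformly sampled tachogram.

    The mean-removed series is (optionally) band-limited to the full
    0.04-0.4 Hz analysis band, then decomposed into LF and HF components with
    separate Butterworth band-pass filters.  Per window, power is the mean of
    the squared component samples; the ratio is LF/HF (NaN where HF power is
    zero).  Windows whose span intersects the edge transient region
    (``1.5 / lf_low`` seconds at each end) are discarded by default, since
    filter start-up transients inflate power.
    """
    if window < 25.0:
        raise ValueError("window must be >= 25 s (one full cycle at 0.04 Hz)")
    if not 0 < hop <= window:
        raise ValueError("need 0 < hop <= window")
    span = (series.values.size - 1) / series.rate
    if span < window:
        raise ValueError(
            f"window ({window} s) is longer than the series span ({span:.1f} s)"
        )

    x = series.values - series.values.mean()
    base = UniformSeries(series.start_time, series.rate, x)
    if broadband_prefilter:
        base = butterworth_filter(
            base, FilterSpec(lf_band[0], hf_band[1], order, zero_phase)
        )
    lf = butterworth_filter(base, FilterSpec(*lf_band, order, zero_phase)).values
    hf = butterworth_filter(base, FilterSpec(*hf_band, order, zero_phase)).values

    t0 = series.start_time
    t_end = t0 + span
    half = window / 2.0
    margin = 1.5 / lf_band[0] if drop_transient_windows else 0.0

    centers = []
    c = t0 + half
    while c <= t_end - half + _EPS:
        if c - half >= t0 + margin - _EPS and c + half <= t_end - margin + _EPS:
            centers.append(c)
        c += hop
    if not centers:
        raise ValueError(
            "no analysis windows survive the transient margin; use a longer "
            "recording or drop_transient_windows=False"
        )

    times = series.times
    lf_power = np.empty(len(centers))
    hf_power = np.empty(len(centers))
    for i, c in enumerate(centers):
        mask = (times >= c - half - _EPS) & (times <= c + half + _EPS)
        lf_power[i] = np.mean(lf[mask] ** 2)
        hf_power[i] = np.mean(hf[mask] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hf_power > 0, lf_power / np.where(hf_power > 0, hf_power, 1.0), np.nan)
    if np.any(hf_power <= 0):
        warnings.warn("windows with zero HF power: ratio undefined (NaN)", stacklevel=2)
    return BandPowerTrack(
        np.asarray(centers), lf_power, hf_power, ratio,
        window_length=window, hop=hop,
    )


def segment_mean_ratio(
    track: BandPowerTrack,
    bounds: tuple[float, float],
    segment: str | None = None,
) -> SegmentRatio:
    """Mean and SD of windowed LF/HF ratios inside a half-open segment.

    A window belongs to the segment when its *center* falls in
    ``[start, end)``; the half-open convention means no window is counted in
    two adjacent segments.  SD uses the n-1 denominator (0.0 for a single
    window).  Windows with undefined (NaN) ratio are excluded with a warning.
    """
    start, end = bounds
    if end <= start:
        raise ValueError("segment end must exceed segment start")
    name = segment if segment is not None else f"[{start:g}, {end:g})"
    mask = (track.window_centers >= start) & (track.window_centers < end)
    if not np.any(mask):
        raise ValueError(f"no HRV windows inside segment {name}")
    ratios = track.ratio[mask]
    defined = ratios[np.isfinite(ratios)]
    if defined.size < ratios.size:
        warnings.warn(
            f"{ratios.size - defined.size} undefined ratio window(s) excluded "
            f"from segment {name}",
            stacklevel=2,
        )
    if defined.size == 0:
        raise ValueError(f"all ratio windows undefined in segment {name}")
    mean = float(np.mean(defined))
    sd = float(np.std(defined, ddof=1)) if defined.size >= 2 else 0.0
    return SegmentRatio(mean=mean, sd=sd, n_windows=int(defined.size), segment=segment)
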