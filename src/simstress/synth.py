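"""Synthetic study data with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* RR interval series with controllable LF and HF sinusoidal modulation
  ("beat-domain" model: the interval value is modulated at the beat's
  occurrence time, so the analytic band powers amp^2/2 are exact ground
  truth for the interpolated tachogram);
* ectopic-beat corruption (short/long couplets that preserve total time),
  the canonical artifact a median filter removes;
* 5-point Likert batteries with per-item location shifts (logistic latent
  variable cut into five symmetric bins, so a zero shift gives an exact
  midpoint median);
* 20-item STAI-Y1 response sets whose scored totals hit a target mean/SD;
* complete multi-participant two-condition (simulated vs. real audition),
  three-segment (baseline, pre-performance, performance) study datasets
  whose per-cell target LF/HF ratios emulate the elevated pre-performance
  arousal pattern — largest before the real audition.

All generators are pure functions of their arguments including ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hrv import HF_BAND, LF_BAND, EcgTrace, RRSeries
from .questionnaires import (
    DEFAULT_STAI_REVERSE_ITEMS,
    SEQ_N_ITEMS,
    STAI_N_ITEMS,
)

__all__ = [
    "RRModulationSpec",
    "StudyDesign",
    "StudyDataset",
    "generate_rr",
    "inject_ectopics",
    "generate_likert",
    "generate_stai",
    "generate_study",
    "make_ecg",
]

#: Latent-logistic cutpoints for 5-point Likert discretization; symmetric
#: about zero so a zero location shift gives median 3 exactly.
_LIKERT_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])

#: Default per-item location shifts for the 19-item evaluation battery:
#: mostly agreeable responses (medians at or above the midpoint), strongest
#: for the skill-development block (items 12-19).
_DEFAULT_SEQ_SHIFTS = (
    0.6, 0.9, 0.6, 1.2, 0.0, 0.6, 0.8, 1.1, 0.5,
    0.9, 0.3, 1.5, 1.6, 0.8, 1.5, 1.5, 1.6, 1.6, 1.7,
)


@dataclass(frozen=True)
class RRModulationSpec:
    """Parameters of the two-band sinusoidal RR modulation model.

    ``rr_k = mean_rr + amp_lf sin(2 pi f_lf t_k) + amp_hf sin(2 pi f_hf t_k)
    + N(0, noise_sd)`` evaluated at each beat time ``t_k``, with the next
    beat at ``t_k + rr_k / 1000``.
    """

    mean_rr: float = 800.0  # ms
    amp_lf: float = 0.0     # ms
    freq_lf: float = 0.10   # Hz, inside the LF band when amp_lf > 0
    amp_hf: float = 0.0     # ms
    freq_hf: float = 0.25   # Hz, inside the HF band when amp_hf > 0
    noise_sd: float = 0.0   # ms
    duration: float = 300.0  # s
    seed: int = 0

    def validate(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.amp_lf, self.amp_hf, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if self.amp_lf > 0 and not LF_BAND[0] <= self.freq_lf <= LF_BAND[1]:
            raise ValueError(
                f"freq_lf={self.freq_lf} outside the LF band {LF_BAND}"
            )
        if self.amp_hf > 0 and not HF_BAND[0] <= self.freq_hf <= HF_BAND[1]:
            raise ValueError(
                f"freq_hf={self.freq_hf} outside the HF band {HF_BAND}"
            )
        if self.amp_lf + self.amp_hf + self.noise_sd >= self.mean_rr:
            raise ValueError(
                "amplitude budget amp_lf + amp_hf + noise_sd must stay below "
                "mean_rr to keep intervals positive"
            )

    @property
    def ground_truth(self) -> dict[str, float]:
        """Analytic band powers of the modulation (ms^2) and their ratio."""
        lf = self.amp_lf**2 / 2.0
        hf = self.amp_hf**2 / 2.0
        return {
            "lf_power_ms2": lf,
            "hf_power_ms2": hf,
            "ratio": lf / hf if hf > 0 else float("nan"),
        }


def generate_rr(
    spec: RRModulationSpec,
    participant_id: str | None = None,
    segment: str | None = None,
) -> tuple[RRSeries, dict[str, float]]:
    """Generate an RR series with known spectral ground truth.

    Returns the series (covering at least ``spec.duration`` seconds) together
    with the analytic band powers (amp^2/2 per modulation).  Identical spec
    (including seed) gives bitwise-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w_lf = 2.0 * np.pi * spec.freq_lf
    w_hf = 2.0 * np.pi * spec.freq_hf
    times = [0.0]
    intervals: list[float] = []
    t = 0.0
    while t < spec.duration:
        rr = spec.mean_rr
        if spec.amp_lf > 0:
            rr += spec.amp_lf * np.sin(w_lf * t)
        if spec.amp_hf > 0:
            rr += spec.amp_hf * np.sin(w_hf * t)
        if spec.noise_sd > 0:
            rr += rng.normal(0.0, spec.noise_sd)
        if rr <= 0:
            raise ValueError(
                f"generated nonpositive interval ({rr:.1f} ms) at t={t:.2f} s: "
                f"amplitude budget amp_lf={spec.amp_lf} + amp_hf={spec.amp_hf} "
                f"+ noise_sd={spec.noise_sd} too large for mean_rr={spec.mean_rr}"
            )
        intervals.append(rr)
        t += rr / 1000.0
        times.append(t)
    series = RRSeries(
        np.asarray(times), np.asarray(intervals),
        participant_id=participant_id, segment=segment,
    )
    return series, spec.ground_truth


def inject_ectopics(
    rr: RRSeries,
    rate: float,
    magnitude: float = 0.5,
    seed: int = 0,
) -> tuple[RRSeries, np.ndarray]:
    """Corrupt an RR series with ectopic-beat couplets.

    Each selected beat's interval is shortened by ``magnitude`` (a fraction
    of its value) and the following interval lengthened by the same amount,
    so total elapsed time is preserved exactly.  Selected positions are never
    adjacent (a couplet occupies two intervals).  Returns the corrupted
    series and the indices of the shortened intervals.
    """
    if not 0 <= rate < 0.2:
        raise ValueError("ectopic rate must be in [0, 0.2)")
    if not 0 < magnitude < 1:
        raise ValueError("magnitude must be in (0, 1)")
    n = rr.intervals.size
    if n == 0:
        raise ValueError("cannot inject ectopics into an empty series")
    rng = np.random.default_rng(seed)
    draws = rng.random(max(n - 1, 0)) < rate
    new = rr.intervals.copy()
    indices: list[int] = []
    prev = -2
    for i in np.nonzero(draws)[0]:
        if i == prev + 1:  # keep couplets disjoint
            continue
        delta = magnitude * new[i]
        new[i] -= delta
        new[i + 1] += delta
        indices.append(int(i))
        prev = i
    import warnings

    with warnings.catch_warnings():
        # couplet intervals may legitimately leave the plausible range
        warnings.simplefilter("ignore")
        corrupted = RRSeries.from_intervals(
            new, t0=float(rr.beat_times[0]),
            participant_id=rr.participant_id, segment=rr.segment,
        )
    return corrupted, np.asarray(indices, dtype=int)


def generate_likert(
    n: int,
    item_shifts: Sequence[float] = _DEFAULT_SEQ_SHIFTS,
    seed: int = 0,
    condition: str = "simulated_audition",
) -> pd.DataFrame:
    """Generate an n x 19 five-point Likert battery in long format.

    Each response discretizes a logistic latent variable with per-item
    location shift through symmetric cutpoints; a larger shift makes
    responses stochastically larger, and a zero shift gives an exact
    population median of 3.  Columns: ``participant_id``, ``condition``,
    ``item``, ``response``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    shifts = np.asarray(item_shifts, dtype=float)
    if shifts.shape != (SEQ_N_ITEMS,):
        raise ValueError(f"item_shifts must have length {SEQ_N_ITEMS}")
    rng = np.random.default_rng(seed)
    latent = shifts[None, :] + rng.logistic(0.0, 1.0, size=(n, SEQ_N_ITEMS))
    responses = 1 + np.searchsorted(_LIKERT_CUTS, latent.ravel(), side="left")
    records = pd.DataFrame(
        {
            "participant_id": np.repeat(
                [f"P{i + 1:02d}" for i in range(n)], SEQ_N_ITEMS
            ),
            "condition": condition,
            "item": np.tile(np.arange(1, SEQ_N_ITEMS + 1), n),
            "response": responses.astype(int),
        }
    )
    return records


def generate_stai(
    n: int,
    target_mean: float,
    target_sd: float,
    seed: int = 0,
    reverse_items: frozenset[int] = DEFAULT_STAI_REVERSE_ITEMS,
) -> pd.DataFrame:
    """Generate STAI-Y1 response vectors whose scored totals hit a target.

    Totals are drawn from N(target_mean, target_sd), clipped to [20, 80] and
    rounded; each total is then spread uniformly at random over the 20 items
    (each item holding 1-4 anxiety-keyed points), and reverse-keyed items are
    stored inverted so that standard scoring recovers the total exactly.
    With ``target_sd=0`` every total equals the (rounded) target, so the
    scale extremes 20 and 80 yield all-minimum / all-maximum vectors.

    Returns a wide DataFrame: ``participant_id`` plus ``q1`` ... ``q20``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 20 <= target_mean <= 80:
        raise ValueError("target_mean outside the attainable range [20, 80]")
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if target_sd > 0:
        totals = rng.normal(target_mean, target_sd, size=n)
    else:
        totals = np.full(n, float(target_mean))
    totals = np.clip(np.rint(totals), 20, 80).astype(int)

    rows = np.empty((n, STAI_N_ITEMS), dtype=int)
    pool = np.repeat(np.arange(STAI_N_ITEMS), 3)  # capacity 3 extra points/item
    for i, total in enumerate(totals):
        excess = int(total) - STAI_N_ITEMS
        chosen = rng.permutation(pool)[:excess]
        keyed = 1 + np.bincount(chosen, minlength=STAI_N_ITEMS)
        raw = keyed.copy()
        for item in reverse_items:
            raw[item - 1] = 5 - keyed[item - 1]
        rows[i] = raw
    df = pd.DataFrame(rows, columns=[f"q{k}" for k in range(1, STAI_N_ITEMS + 1)])
    df.insert(0, "participant_id", [f"P{i + 1:02d}" for i in range(n)])
    return df


def _default_effect_matrix() -> dict[tuple[str, str], float]:
    # Elevated pre-performance arousal, larger before the real audition.
    return {
        ("simulated_audition", "baseline"): 1.2,
        ("simulated_audition", "pre_performance"): 2.5,
        ("simulated_audition", "performance"): 2.0,
        ("real_audition", "baseline"): 1.2,
        ("real_audition", "pre_performance"): 5.0,
        ("real_audition", "performance"): 2.2,
    }


def _default_segment_durations() -> dict[str, float]:
    # 5-min baseline and pre-performance windows; fixed nominal 5-min
    # performance span (real performance lengths vary, synthetic ones don't).
    return {"baseline": 300.0, "pre_performance": 300.0, "performance": 300.0}


def _default_stai_targets() -> dict[str, tuple[float, float]]:
    return {
        "simulated_audition": (32.29, 7.39),
        "real_audition": (37.43, 7.09),
    }


@dataclass
class StudyDesign:
    """Ground-truth design of a synthetic two-condition within-subjects study."""

    n_participants: int = 7
    conditions: tuple[str, ...] = ("simulated_audition", "real_audition")
    segments: tuple[str, ...] = ("baseline", "pre_performance", "performance")
    segment_durations: Mapping[str, float] = field(
        default_factory=_default_segment_durations
    )
    effect_matrix: Mapping[tuple[str, str], float] = field(
        default_factory=_default_effect_matrix
    )
    questionnaire_shifts: tuple[float, ...] = _DEFAULT_SEQ_SHIFTS
    stai_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_stai_targets
    )
    mean_rr: float = 800.0        # ms, population mean resting interval
    mean_rr_sd: float = 50.0      # ms, between-participant spread
    amp_hf: float = 20.0          # ms, HF (respiratory) modulation amplitude
    freq_lf: float = 0.10         # Hz
    freq_hf: float = 0.25         # Hz
    noise_sd: float = 5.0         # ms, broadband beat-to-beat noise
    ratio_sigma: float = 0.25     # log-normal spread of per-cell target ratios
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for cond in self.conditions:
            for seg in self.segments:
                if (cond, seg) not in self.effect_matrix:
                    raise ValueError(f"effect_matrix missing cell {(cond, seg)}")
                if self.effect_matrix[(cond, seg)] <= 0:
                    raise ValueError(f"target ratio must be positive for {(cond, seg)}")
        for seg in self.segments:
            if self.segment_durations.get(seg, 0) <= 0:
                raise ValueError(f"segment duration must be positive for {seg!r}")


@dataclass
class StudyDataset:
    """Everything the pipeline consumes, with generation ground truth attached."""

    design: StudyDesign
    rr: dict[tuple[str, str, str], RRSeries]          # (participant, condition, segment)
    rr_truth: dict[tuple[str, str, str], dict[str, float]]
    likert: pd.DataFrame                               # long format, both conditions
    stai: pd.DataFrame                                 # wide + participant_id, condition

    @property
    def participants(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.design.n_participants)]


def generate_study(design: StudyDesign) -> StudyDataset:
    """Generate a full synthetic study dataset.

    Per participant, condition and segment, an RR series is generated whose
    LF modulation amplitude is chosen so the analytic LF/HF ratio equals the
    design's target for that cell times a per-cell log-normal multiplier
    (between/within-participant variability).  Questionnaire batteries and
    STAI responses are generated per condition.  Deterministic in
    ``design.seed``.
    """
    design.validate()
    master = np.random.default_rng(design.seed)
    participants = [f"P{i + 1:02d}" for i in range(design.n_participants)]
    mean_rrs = master.normal(design.mean_rr, design.mean_rr_sd, design.n_participants)
    mean_rrs = np.clip(mean_rrs, 500.0, 1200.0)

    rr: dict[tuple[str, str, str], RRSeries] = {}
    rr_truth: dict[tuple[str, str, str], dict[str, float]] = {}
    for p_idx, pid in enumerate(participants):
        for cond in design.conditions:
            for seg in design.segments:
                target = design.effect_matrix[(cond, seg)]
                jitter = float(np.exp(master.normal(0.0, design.ratio_sigma)))
                cell_ratio = target * jitter
                amp_lf = design.amp_hf * np.sqrt(cell_ratio)
                spec = RRModulationSpec(
                    mean_rr=float(mean_rrs[p_idx]),
                    amp_lf=float(amp_lf),
                    freq_lf=design.freq_lf,
                    amp_hf=design.amp_hf,
                    freq_hf=design.freq_hf,
                    noise_sd=design.noise_sd,
                    duration=float(design.segment_durations[seg]),
                    seed=int(master.integers(2**31)),
                )
                series, truth = generate_rr(spec, participant_id=pid, segment=seg)
                key = (pid, cond, seg)
                rr[key] = series
                rr_truth[key] = {**truth, "target_ratio": target, "cell_ratio": cell_ratio}

    likert_parts = []
    stai_parts = []
    for cond in design.conditions:
        lik = generate_likert(
            design.n_participants,
            design.questionnaire_shifts,
            seed=int(master.integers(2**31)),
            condition=cond,
        )
        likert_parts.append(lik)
        mean, sd = design.stai_targets[cond]
        st = generate_stai(
            design.n_participants, mean, sd, seed=int(master.integers(2**31))
        )
        st.insert(1, "condition", cond)
        stai_parts.append(st)

    return StudyDataset(
        design=design,
        rr=rr,
        rr_truth=rr_truth,
        likert=pd.concat(likert_parts, ignore_index=True),
        stai=pd.concat(stai_parts, ignore_index=True),
    )


def make_ecg(
    rr: RRSeries,
    fs: float = 250.0,
    spike_width: float = 0.012,
    noise_sd: float = 0.02,
    pad: float = 0.5,
    seed: int = 0,
) -> EcgTrace:
    """Render a spiky synthetic ECG trace from a beat series.

    A unit-amplitude Gaussian bump is placed at each beat time on a uniform
    grid at ``fs`` Hz (extended ``pad`` seconds past the last beat so the
    final complex is not clipped), plus optional baseline noise — enough
    waveform realism to exercise R-peak detection, no more.
    """
    rng = np.random.default_rng(seed)
    t_end = float(rr.beat_times[-1]) + pad
    n = int(np.floor(t_end * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)
    for bt in rr.beat_times:
        lo = max(0, int((bt - 5 * spike_width) * fs))
        hi = min(n, int((bt + 5 * spike_width) * fs) + 1)
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / spike_width) ** 2)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    return EcgTrace(sample_times=t, amplitude=x, rate=fs)
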