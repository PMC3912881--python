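# Methods

This note documents the models, parameter choices and numerical conventions
behind `simstress`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Synthetic RR model

RR intervals are generated in the *beat domain*: the interval beginning at
beat time `t_k` is

```
rr_k = mean_rr + a_LF sin(2π f_LF t_k) + a_HF sin(2π f_HF t_k) + ε_k,
ε_k ~ N(0, σ²),   t_{k+1} = t_k + rr_k / 1000
```

with `mean_rr` in ms and times in s. Because the downstream analysis treats
RR as a signal to be interpolated at the beat times, this model makes the
band powers analytic: a modulation of amplitude `a` carries exactly `a²/2`
ms² of power in its band. That is the ground truth every parameter-recovery
test compares against. A full integral-pulse (IPFM) model would be more
physiological but has no closed-form band power; the beat-domain form keeps
the oracle exact.

Defaults: `mean_rr` 800 ms (75 bpm), LF modulation at 0.10 Hz, HF at
0.25 Hz (a typical breathing rate), beat-to-beat noise SD 5 ms. Amplitudes
must satisfy `a_LF + a_HF + σ < mean_rr`; any generated non-positive
interval aborts with a diagnostic naming the amplitude budget.

Ectopic corruption is the canonical couplet: a selected interval is
shortened by a fraction `m` and the following interval lengthened by the
same amount, so cumulative time is conserved exactly and the artifact is
precisely the kind a median-based cleaner removes. Selected positions are
never adjacent.

### Study-level generator

`generate_study` emulates a two-condition (simulated vs. real audition),
three-segment (baseline, pre-performance, performance) within-subjects
design. Per participant × condition × segment cell, the target LF/HF ratio
from the design's effect matrix is multiplied by a log-normal jitter
(σ = 0.25 on the log scale) representing between-participant and
between-occasion variability, and the LF amplitude is set to
`a_HF √(target × jitter)` so the analytic ratio of the generated series hits
the jittered target. Default effect matrix: baseline ≈ 1.2 in both
conditions, performance ≈ 2, pre-performance 2.5 (simulated) vs. 5.0
(real) — a resting sympatho-vagal balance, moderate arousal during playing,
and the strongest elevation in the minutes before the real audition.
Segments default to 300 s (5 min), matching the usual short-term HRV
recording convention for baseline and pre-performance windows; real
performance spans vary in length, synthetic ones use a fixed configurable
duration.

STAI-Y1 vectors are generated total-first: the scored total is drawn from
N(target mean, target SD), clipped to [20, 80] and rounded, then spread
uniformly over the 20 items (1–4 anxiety-keyed points each), and
reverse-keyed items are stored inverted so standard scoring recovers the
total exactly. With SD 0 the extreme targets 20 and 80 produce the
all-minimum and all-maximum vectors. Default condition targets
(32.29 ± 7.39 simulated, 37.43 ± 7.09 real) sit in the moderate state-
anxiety range typical of advanced music students before an audition.

Likert responses discretize a logistic latent variable with per-item
location shift through the symmetric cutpoints (−1.5, −0.5, 0.5, 1.5); the
symmetry makes a zero shift give an exact population median of 3, which is
the null of the midpoint test and hence directly testable. Larger shifts
give stochastically larger responses.

Every generator is a pure function of its arguments including the seed;
study-level sub-streams are drawn deterministically from one master
generator.

## HRV chain

1. **Artifact handling.** Two cleaners are provided. `median_filter_rr` is
   the plain moving median (replicate padding, beat times rebuilt by
   cumulative summation) — the classical ectopic remover, and the operation
   the repair benchmark exercises (at 2 % corruption, kernel 5, ≥ 90 % of
   couplets are restored to within 5 %). The *pipeline default*, however, is
   `repair_ectopics`: an interval is replaced by its kernel-5 local median
   only when it deviates from that median by more than 20 %. The reason is
   spectral: at 75 bpm a 5-beat window spans an entire 0.25 Hz respiratory
   cycle, so an unconditional moving median flattens the HF modulation
   itself and inflates LF/HF by an order of magnitude. The gated variant is
   the identity on clean data (physiological modulation stays well under the
   20 % threshold at realistic amplitudes) while ectopic couplets, which
   deviate by ~50 %, are still removed. Implausible intervals (outside
   200–3000 ms) are flagged with a warning, not deleted.
2. **Resampling.** Natural cubic spline through the knots
   (beat time, interval), evaluated on a uniform 4 Hz grid spanning the
   knots. The spline passes through every knot exactly; at 4 Hz the grid
   oversamples the 0.4 Hz upper band edge tenfold.
3. **Band decomposition.** The mean-removed tachogram is band-limited to
   0.04–0.4 Hz and split into LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz)
   components, each with a 4th-order Butterworth band-pass applied
   forward-backward (zero phase). Zero-phase filtering keeps windowed powers
   time-aligned with segment boundaries; a causal filter's group delay
   (tens of seconds at these frequencies) would smear power across segment
   joins. The cost is doubled attenuation in dB, which only sharpens the
   band split.
4. **Windowed power.** Per window (default 60 s — 2.4 cycles of the lowest
   LF frequency — hopped by 30 s), power is the mean squared amplitude of
   each component (time-domain band power, matching the filter-based rather
   than periodogram-based formulation); the ratio is LF/HF, flagged
   undefined (NaN) where HF power is zero. Windows whose span intersects
   the first or last `1.5 / 0.04 = 37.5` s are discarded by default because
   filter edge transients inflate power; a 300 s segment retains 5 windows.
   Consequently a segment must be ≈ 165 s or longer to contain any
   transient-free window.
5. **Segment summary.** Windows belong to a segment when their *centre*
   falls in the half-open interval `[start, end)` — no window is counted
   twice at a join. The summary is the arithmetic mean and n−1 SD of the
   window ratios.

R-peak detection (for synthetic ECG input) thresholds local maxima midway
between the trace mean and maximum with a refractory distance (default
0.3 s); it is deliberately simple — the synthetic ECG has unit-amplitude
spikes, and real devices do their own detection upstream.

## Inference

* **Wilcoxon signed-rank, one sample.** Differences from μ₀; zeros removed
  before ranking (Wilcoxon's convention; Pratt's zero-rank method is
  available as an option); average ranks for ties. The exact null
  distribution of the positive-rank sum over all 2ⁿ sign assignments is
  computed by shift-and-add convolution over doubled ranks (integers even
  under average-rank ties); it is used for n ≤ 12 always, and up to n = 25
  when the ranks are untied. Beyond that, a normal approximation with
  tie-corrected variance and a 0.5 continuity correction is used; at n = 25
  the two agree to better than 0.01 absolute. The default alternative is
  two-sided — conservative when the direction is not pre-registered — with
  one-sided options. No multiple-testing correction is applied across items
  by default (the per-item tests are reported as a battery; Holm adjustment
  can be layered on by the caller).
* **Paired t.** `t = mean(d) / (sd(d)/√n)`, df = n − 1, two-sided p.
  Zero-variance differences raise rather than return ±∞.
* **Repeated-measures ANOVA.** Classical two-factor within-subjects
  decomposition with partitioned error strata: each effect (time, audition,
  interaction) is tested against its own participant × effect interaction
  mean square. Degrees of freedom at n participants: (a−1, (a−1)(n−1)),
  (b−1, (b−1)(n−1)), ((a−1)(b−1), (a−1)(b−1)(n−1)). Uncorrected df are the
  default (reproducing the standard reporting convention for small
  within-subjects designs); a Greenhouse–Geisser epsilon correction is
  available via `sphericity_correction="gg"`. The effect and error sums of
  squares partition the total corrected SS exactly; degenerate all-equal
  data yield SS = 0 and a flagged undefined F. With two levels and no
  second factor the F statistic equals the paired t² identically.
* **Shapiro–Wilk screening** delegates to the Royston-algorithm
  implementation in scipy behind a validated surface (it is a screening
  step, not a headline statistic); constant input is rejected.

## Calibration experiments (what the tests show)

* Exact Wilcoxon p equals brute-force 2ⁿ enumeration (independent oracle)
  for hundreds of tied integer samples at n ≤ 12.
* Under a symmetric continuous null at n = 12 the two-sided exact test
  rejects at ≈ 4.2 % at α = 0.05 (the discreteness of the null makes the
  attainable size slightly conservative); each ANOVA effect rejects at
  ≈ 5 % under Gaussian null cells at n = 7 (2000 replicates each).
* Noise-free two-band modulation over 300 s recovers segment-mean LF/HF
  within ±15 % of the analytic a²/b² (measured ≈ +2 %, dominated by
  spline and filter pass-band ripple), and single-band power within ±15 %
  of a²/2.

These are *pipeline correctness* results, not claims about real data: the
generator's sinusoid-plus-white-noise model has neither the 1/f background,
the non-stationarity, nor the respiratory frequency wander of real HRV, and
the Likert/STAI generators model marginal distributions, not inter-item
correlation structure. Passing tests show the chain measures what it claims
to measure where the truth is known — they do not validate LF/HF as a
stress construct, a debate outside this package's scope.

## Numerical conventions and edge cases

* Times in seconds from recording start; intervals in ms; powers in ms²;
  ratios dimensionless.
* Interval/beat-time consistency is enforced at construction (1e-3 ms
  tolerance); series are immutable through the chain (each stage returns a
  new object).
* Window membership and segment bounds use half-open intervals with a 1e-9 s
  tolerance against floating-point grid drift.
* The STAI reverse-keyed set is a configuration input (the published
  instrument is copyrighted and its keying cannot be shipped verbatim);
  the default is the conventional ten positively-worded items
  {1, 2, 5, 8, 10, 11, 15, 16, 19, 20}. Scoring refuses missing items —
  no imputation anywhere in the package.
* The study config is strict YAML: unknown keys raise, so typos cannot
  silently fall back to defaults. Reports embed a config hash and seed and
  regenerate byte-identically.

## Known limitations

* No Welch/AR spectral estimation, VLF band, or time-domain HRV suite
  (SDNN/RMSSD); the band-power track is filter-based by design.
* The ECG path is minimal (synthetic spike trains); no real-device formats
  (EDF/WFDB) are parsed.
* `generate_study` draws each condition's questionnaire battery
  independently; cross-condition correlation of an individual's response
  style is not modelled.
* The exact Wilcoxon path is O(n · Σranks) in memory/time and capped at
  n = 25; larger samples use the (well-calibrated) normal approximation.
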