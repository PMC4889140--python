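# Methods

This note documents the detection model, the synthetic data it is
validated against, and the numerical choices made where the procedure
left room for interpretation.

## Signal model and conventions

A trial is a single EMG channel (mV) sampled at a known rate (default
5 kHz) containing one TMS pulse. Indices are 0-based, windows half-open
`[start, end)`, and a duration in ms is `(idx_b − idx_a) / fs × 1000`.
All threshold comparisons in the detectors are strict (`>`): a tie does
not trigger, the next sample does. The TMS artifact is the temporal
benchmark; it is taken from the acquisition trigger when present,
otherwise from the global maximum of the rectified signal (the stimulus
transient dominates every other feature by design of the recording).

The frame of interest spans 60 ms before to 420 ms after the artifact.
The 420 ms are counted from the artifact, not from the window start; the
alternative reading would shorten the usable post-stimulus window by
60 ms and make the 400 ms offset search window impossible to honour.

## Pre-pulse baseline statistics

Both detection thresholds are subject- and contraction-specific,
derived from the voluntary EMG before the pulse (for the first trial of
a recording: everything from the start of the record; in general, from
the end of the previous frame of interest). The final 2 ms before the
artifact are excluded as a guard band against stimulus leakage — the
procedure itself is silent on this, and 2 ms is comfortably larger than
the artifact's rise at 5 kHz while discarding almost no baseline data.
A minimum of 40 ms of baseline is required.

* Mean negative peak `v̄⁻`: the mean of all strict local minima with
  negative value ("negative peaks"); plateaus take their first index.
  No rectification is involved.
* Mean absolute derivative `d̄`: the mean of `|x[i+1] − x[i]|` of the
  high-pass filtered baseline.

`AnalysisConfig.prepulse_max_ms` (default `None` = all available data)
optionally caps the baseline segment at a fixed length before the
artifact. A fixed-length baseline makes the detector exactly
translation-equivariant, which the equivariance tests exploit; with the
default, shifting a finite record necessarily changes the baseline
segment and thresholds may move by one sample.

## Filtering

The stated cut-off of 0.016 is dimensionless; it is interpreted in the
MATLAB convention as a fraction of the Nyquist frequency (40 Hz at
5 kHz) and stored in the config so users at other sampling rates can
hold the physical cut-off fixed. The filter family and order are not
prescribed anywhere; a 2nd-order Butterworth applied forward-backward
(`sosfiltfilt`) is used because zero-phase filtering preserves
onset/offset timing, which is the entire point of the pipeline. The
effective magnitude response is therefore |H|², which the filter tests
account for.

## Detection rules

* **MEP minimum**: argmin of the raw signal in [artifact + 5 ms,
  artifact + 45 ms]; ties to the earliest index. The window follows the
  observation that the MEP trough sits near 25 ms post-artifact.
* **CSP onset**: scanning backward in time from the MEP minimum, the
  first sample `> v̄⁻`. This index is simultaneously the MEP onset; the
  reported CSP includes the MEP. For a conventional biphasic MEP the
  backward scan can stop at the zero-crossing between the positive peak
  and the trough rather than at the true onset; the rule is implemented
  literally and the generator's default MEP shape is monophasic-negative
  (single descent, recovery, small rebound) for which the rule is
  well-posed. A biphasic shape is available for stress testing and no
  recovery is asserted there.
* **MEP offset** (matched filter, default): similarity is the absolute
  Pearson correlation between the de-meaned template and each de-meaned
  sliding window at and after the artifact — invariant to amplitude and
  polarity. Events are local maxima of the trace strictly above the
  0.95 default threshold, greedily selected non-overlapping in order of
  decreasing similarity; the first event's position plus the template
  length is the offset. Mapping "event + template length" to the offset
  is the natural reading when the template spans onset-to-offset of an
  exemplar MEP. The filter runs in the signal domain; the spectrogram
  (Hamming segments, 50 % overlap, across-frequency power sums) is
  retained as the display used to choose templates. With 20–450 Hz
  background EMG at realistic SNR, the measured maximum similarity of a
  template against 50 MEP-free frames is ≈ 0.75, well below threshold,
  so MEP-less trials reliably fail this stage.
* **CSP offset**: in [MEP offset + 10 ms, + 400 ms] (clipped to the
  frame with a warning), the first strict exceedance of `0.75 · d̄` by
  the 30-sample *trailing* moving average of the rectified derivative of
  the high-pass filtered frame. The average is trailing so the crossing
  has an unambiguous latency; only fully populated windows inside the
  search region can trigger, so the first 29 samples cannot fire. If
  fewer than 30 samples remain after clipping, the trial fails.
* **Plausibility gate**: detected durations `≤ MEP duration + 5 ms` are
  flagged `implausible`. Note a structural property: whenever all
  stages succeed, the detected offset is at least MEP offset + 10 ms +
  the moving-average warm-up, so the detected duration always exceeds
  MEP + 5 ms and the gate cannot fire. In practice every flag on real
  pipelines is `detection_failed` with the failing stage recorded; the
  gate remains as a guard for configurations with a larger margin or a
  shorter search offset. Trials with *continued* voluntary activity
  (MEP present but no silent period) therefore pass the gate with a
  short (~40 ms) duration — a limitation inherited from the rule set
  and surfaced by a dedicated test and the generator's `no_csp` stress
  mode.

## Synthetic trial generator

The generator emulates the recording conditions the detector targets:
tonic contraction at ~20 % MVC, 5 kHz sampling, one pulse per trial.

* Background EMG: Gaussian noise band-passed to 20–450 Hz (the surface
  EMG energy band within the hardware's 5 Hz–5 kHz acquisition band),
  rescaled to exactly 0.15 mV RMS — a plausible 20 %-MVC interference
  pattern level.
* Artifact: 8 mV raised-cosine transient of 1 ms at 100 ms.
* MEP: default monophasic-negative waveform, 3 mV peak, 25 ms long,
  20 ms after the artifact; the trough sits at 30 % of the duration
  (≈ 27.5 ms post-artifact). The ground-truth minimum index is the
  argmin of the *composite* signal within the MEP span.
* Silent period: the background is multiplicatively suppressed to 3 %
  of tonic (motor-unit silence is a gain process, not added silence)
  from the MEP offset until `return_ramp` (20 ms) before the CSP
  offset, where the amplitude ramps linearly back to tonic. The
  ground-truth CSP offset marks the *completion* of this resumption:
  the measured endpoint is the reversion to **continuous** voluntary
  activity (the SP2 convention), which a gradual resumption reaches at
  the ramp's end, not at its first flicker. The 20 ms ramp itself is a
  modeling choice — no quantitative description of resumption steepness
  exists to constrain it — and with it the 75 % derivative crossing
  lands ~2–3 ms before the true offset (the trailing-average crossing
  point), measured as a −2.2 ms mean duration bias with 4.4 ms SD over
  200 trials.
* Per-trial jitter in datasets: Gaussian latency (SD 1 ms), log-normal
  amplitudes (σ = 0.1), Gaussian CSP duration (SD 10 ms), truncated to
  keep the construction invariants; the validation design instead draws
  CSP durations uniformly from 100–250 ms, spanning the physiological
  range.
* Corrupted trials (default mode): *failure to evoke* — the artifact
  fires but no MEP is inserted and voluntary EMG continues, which is
  the physiologically coherent reading of "no MEP" (no MEP implies no
  silent period). These are flagged by the matched filter with ≈ 100 %
  sensitivity at 0 % false-positive rate on clean trials. The `no_csp`
  stress mode (MEP without suppression) exists to demonstrate the
  gate's structural blindness documented above and is not part of the
  default mix.

What passing recovery tests show — and what they do not: the synthetic
background is stationary Gaussian noise; real EMG has motor-unit
structure, occasional movement artifacts, mains interference and
non-stationary contraction levels. Recovery on synthetic trials
validates the *rules and their implementation*, not field performance
on arbitrary recordings.

## Agreement statistics

ICC(A,1) (two-way, absolute agreement, single measure) is computed
directly from the ANOVA mean squares rather than delegated, so the
brute-force oracle comparison in the tests is meaningful; pingouin
serves as an independent cross-check (agreement to ~5e-16). The
mixed-vs-random model distinction changes only the interpretation, not
the point estimate. The CI uses the McGraw–Wong F-based method with a
Satterthwaite approximation. Zero between-subject variance leaves the
coefficient undefined and raises an error rather than returning 0.
Identical raters yield the degenerate interval (1, 1). Bland–Altman
limits use the sample SD (n−1) and the conventional 1.96 multiplier.

A manual-vs-automated timing comparison (wall-clock medians) is out of
scope: it is hardware-dependent and carries no algorithmic content.

## Problem sizes

The test suite and acceptance script use 100–200 clean trials for
recovery, 50 × 10-trial datasets for gate behaviour, 50 trials for
equivariance, and ≥ 1000 random instances per brute-force oracle —
sizes at which every reported fraction is stable to a few percent
across seeds while the whole suite runs in seconds.

## Known limitations

* CSP without a preceding MEP is not detectable (the pipeline is
  anchored on the MEP), matching the scope of the original rule set.
* The gate cannot flag continued-activity trials (see above).
* The backward-scan onset rule is biased for biphasic MEPs.
* EDF input is not supported; datasets are delimited text + JSON
  sidecar.
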