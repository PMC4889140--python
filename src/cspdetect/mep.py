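"""MEP minimum, onset and offset detection.

The MEP minimum is the global minimum of the raw signal in a 5-45 ms
window after the TMS artifact.  The MEP *onset* is shared with the CSP
onset (see :mod:`cspdetect.csp`).  The MEP *offset* — and hence the MEP
duration — can be determined three ways:

``matched_filter``
    A user-chosen MEP exemplar is slid over the frame; positions whose
    normalized correlation with the template exceeds the similarity
    threshold (default 0.95) are events, and the offset is the event
    position plus the template length.  This is the recommended method.
``lowpass_peak``
    The frame is low-pass filtered and the offset is the second peak of
    the rectified output with amplitude >= 2 mV.  Kept for insight only:
    it assumes a clean one-wavelength slow sinusoid, which many real
    recordings do not show, so it should not be used for analysis.
``fixed``
    A fixed 25 ms MEP duration; fast but ignores subject-specific MEP
    shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .config import AnalysisConfig, ms_to_samples, samples_to_ms
from .errors import (
    DetectionError,
    MethodError,
    ParameterError,
    TemplateMatchError,
)
from .signal_prep import FrameOfInterest, butterworth_filter


@dataclass
class MEPTemplate:
    """User-selected MEP exemplar (onset-to-offset segment of one trial)."""

    samples: np.ndarray
    source_trial_id: str
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        dur = samples_to_ms(self.samples.size, self.fs)
        if not 5.0 <= dur <= 60.0:
            raise ParameterError(
                f"template must span 5-60 ms of signal, got {dur:.1f} ms"
            )

    def __len__(self):
        return self.samples.size


@dataclass
class MEPResult:
    """Detected MEP landmarks (absolute trial indices) and duration."""

    min_idx: int
    onset_idx: int
    offset_idx: int
    duration_ms: float
    method: str
    similarity: Optional[float] = None


def find_mep_minimum(
    frame: FrameOfInterest, config: AnalysisConfig = AnalysisConfig()
) -> int:
    """Global minimum of the raw signal 5-45 ms after the artifact.

    Returns an absolute trial index; ties break to the earliest sample
    (the MEP trough typically sits near 25 ms post-artifact).
    """
    fs = frame.sampling_rate
    lo_ms, hi_ms = config.mep_min_search_ms
    lo = frame.artifact_offset + ms_to_samples(lo_ms, fs)
    hi = frame.artifact_offset + ms_to_samples(hi_ms, fs)
    hi_eff = min(hi, frame.samples.size)
    if samples_to_ms(hi_eff - lo, fs) < 20.0:
        raise DetectionError(
            "MEP-minimum search window truncated below 20 ms", stage="mep_min"
        )
    return frame.start_idx + lo + int(np.argmin(frame.samples[lo:hi_eff]))


def match_template(
    frame: FrameOfInterest,
    template: MEPTemplate,
    similarity_threshold: float,
) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, float]]]:
    """Normalized-correlation matched filter.

    The template is compared with every sliding window starting at or
    after the artifact.  Similarity is the absolute Pearson correlation
    between template and window (each de-meaned per window), which is
    invariant to the amplitude and polarity of the signal.  Events are
    local maxima of the trace above ``similarity_threshold``, greedily
    selected non-overlapping in order of decreasing similarity.

    Returns ``(positions, trace, events)``: absolute start indices of the
    compared windows, their similarities in [0, 1], and the event list
    sorted by position.
    """
    t = template.samples
    m = t.size
    if m >= frame.samples.size:
        raise ParameterError("template must be shorter than the frame")
    if not 0 < similarity_threshold <= 1:
        raise ParameterError("similarity_threshold must lie in (0, 1]")
    start = frame.artifact_offset
    windows = sliding_window_view(frame.samples, m)[start:]
    tc = t - t.mean()
    nt = np.linalg.norm(tc)
    if nt == 0:
        raise ParameterError("template is constant")
    wc = windows - windows.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(wc, axis=1) * nt
    num = np.abs(wc @ tc)
    trace = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    np.clip(trace, 0.0, 1.0, out=trace)
    positions = frame.start_idx + start + np.arange(trace.size)

    peaks, _ = sps.find_peaks(trace)
    # find_peaks excludes endpoints; admit them when they dominate their
    # neighbour (a template copy flush against the frame edge)
    edge = [
        i
        for i in (0, trace.size - 1)
        if trace.size > 1 and trace[i] > trace[1 if i == 0 else -2]
    ]
    candidates = [
        i
        for i in set(peaks.tolist()) | set(edge)
        if trace[i] > similarity_threshold or trace[i] == 1.0
    ]
    candidates.sort(key=lambda i: trace[i], reverse=True)
    chosen: List[int] = []
    for i in candidates:
        if all(abs(i - j) >= m for j in chosen):
            chosen.append(i)
    events = sorted((int(positions[i]), float(trace[i])) for i in chosen)
    return positions, trace, events


def detect_mep(
    frame: FrameOfInterest,
    onset_idx: int,
    min_idx: int,
    config: AnalysisConfig = AnalysisConfig(),
    template: Optional[MEPTemplate] = None,
) -> MEPResult:
    """Determine the MEP offset and duration by the configured method.

    ``onset_idx`` comes from the CSP-onset rule (the CSP onset *is* the
    MEP onset) and ``min_idx`` from :func:`find_mep_minimum`; both are
    absolute trial indices.
    """
    fs = frame.sampling_rate
    method = config.mep_method
    similarity = None
    if method == "matched_filter":
        if template is None:
            raise ParameterError("matched_filter requires a template")
        _, _, events = match_template(frame, template, config.similarity_threshold)
        if not events:
            raise TemplateMatchError("no MEP matched", stage="mep_offset")
        pos, similarity = events[0]
        offset_idx = pos + len(template)
    elif method == "lowpass_peak":
        y = np.abs(butterworth_filter(frame.samples, config.cutoff_norm, "lowpass"))
        region = y[frame.artifact_offset + 1 :]
        peaks, _ = sps.find_peaks(region, height=config.lowpass_peak_min_mv)
        if peaks.size < 2:
            raise MethodError(
                f"lowpass_peak found {peaks.size} peak(s) >= "
                f"{config.lowpass_peak_min_mv} mV (needs 2); consider the "
                "'fixed' method",
                stage="mep_offset",
            )
        offset_idx = frame.start_idx + frame.artifact_offset + 1 + int(peaks[1])
    elif method == "fixed":
        offset_idx = onset_idx + ms_to_samples(config.fixed_mep_ms, fs)
    else:  # pragma: no cover - config validation forbids this
        raise ParameterError(f"unknown mep_method {method!r}")

    if method != "fixed" and not onset_idx < min_idx < offset_idx:
        raise DetectionError(
            f"inconsistent MEP landmarks (onset {onset_idx}, min {min_idx}, "
            f"offset {offset_idx})",
            stage="mep_offset",
        )
    return MEPResult(
        min_idx=int(min_idx),
        onset_idx=int(onset_idx),
        offset_idx=int(offset_idx),
        duration_ms=samples_to_ms(offset_idx - onset_idx, fs),
        method=method,
        similarity=similarity,
    )


def make_template(
    trial_samples: np.ndarray,
    onset_idx: int,
    offset_idx: int,
    fs: float,
    source_trial_id: str = "",
) -> MEPTemplate:
    """Cut an MEP template from user-marked onset/offset indices."""
    if not 0 <= onset_idx < offset_idx <= len(trial_samples):
        raise ParameterError("template marks out of bounds or inverted")
    return MEPTemplate(
        samples=np.asarray(trial_samples[onset_idx:offset_idx], dtype=float),
        source_trial_id=source_trial_id,
        fs=fs,
    )
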