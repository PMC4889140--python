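"""Shared signal primitives for the CSP pipeline.

The detectors operate on a *frame of interest* — a window from 60 ms
before to 420 ms after the TMS artifact — and on subject-specific
baseline statistics of the pre-pulse EMG (mean negative-peak amplitude,
mean absolute derivative of the high-pass filtered signal).  All windows
are half-open ``[start, end)``, all indexing is 0-based, and durations in
ms are ``(idx_b - idx_a) / fs * 1000``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig, ms_to_samples
from .errors import DetectionError, ParameterError


@dataclass
class EMGTrial:
    """One trial of single-channel surface EMG around a TMS pulse.

    Attributes
    ----------
    samples : ndarray
        Signal in mV.
    sampling_rate : float
        Sampling rate in Hz.
    trigger_idx : int, optional
        Sample index of the TMS pulse if the acquisition recorded one;
        when absent the artifact is localized from the signal itself.
    trial_id : str
    """

    samples: np.ndarray
    sampling_rate: float
    trigger_idx: Optional[int] = None
    trial_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.trigger_idx is not None and not (
            0 <= self.trigger_idx < self.samples.size
        ):
            raise ParameterError("trigger_idx out of bounds")


@dataclass
class FrameOfInterest:
    """Analysis window around one TMS artifact.

    ``samples`` is a view of the parent trial on ``[start_idx, end_idx)``.
    """

    start_idx: int
    artifact_idx: int
    end_idx: int
    samples: np.ndarray
    sampling_rate: float

    @property
    def artifact_offset(self) -> int:
        """Artifact position relative to the frame start."""
        return self.artifact_idx - self.start_idx


@dataclass
class PrePulseStats:
    """Baseline statistics of the voluntary pre-pulse EMG.

    ``mean_negative_peak`` (mV, <= 0) thresholds the CSP-onset backward
    scan; ``mean_abs_derivative_hp`` (mV/sample, >= 0) scales the
    CSP-offset moving-average threshold.
    """

    mean_negative_peak: float
    mean_abs_derivative_hp: float
    n_peaks: int
    segment: tuple = field(default=(0, 0))


def locate_tms_artifact(trial: EMGTrial) -> int:
    """Locate the TMS stimulus artifact.

    Returns the recorded trigger index when present; otherwise the index
    of the global maximum of the rectified signal (the stimulus transient
    dwarfs both the MEP and the voluntary EMG).
    """
    if trial.trigger_idx is not None:
        return int(trial.trigger_idx)
    x = np.abs(trial.samples)
    if np.ptp(trial.samples) == 0:
        raise DetectionError("constant signal with no trigger", stage="artifact")
    return int(np.argmax(x))


def extract_frame(
    trial: EMGTrial, artifact_idx: int, config: AnalysisConfig = AnalysisConfig()
) -> FrameOfInterest:
    """Cut the frame of interest around the artifact.

    The frame runs from ``pre_ms`` before the artifact to ``post_ms``
    after it, clipped to the trial bounds (with a warning when clipping
    occurs).  An artifact closer than 5 ms to the end of the trial leaves
    no room for an MEP and is an error.
    """
    fs = trial.sampling_rate
    n = trial.samples.size
    if not 0 <= artifact_idx < n:
        raise ParameterError("artifact_idx out of bounds")
    if n - artifact_idx < ms_to_samples(5.0, fs):
        raise DetectionError("artifact too close to end of trial", stage="frame")
    start = artifact_idx - ms_to_samples(config.pre_ms, fs)
    end = artifact_idx + ms_to_samples(config.post_ms, fs)
    if start < 0 or end > n:
        warnings.warn(
            f"frame of interest [{start}, {end}) truncated to trial bounds "
            f"[0, {n})",
            stacklevel=2,
        )
        start = max(start, 0)
        end = min(end, n)
    return FrameOfInterest(
        start_idx=start,
        artifact_idx=artifact_idx,
        end_idx=end,
        samples=trial.samples[start:end],
        sampling_rate=fs,
    )


def butterworth_filter(samples: np.ndarray, cutoff_norm: float, mode: str) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth high- or low-pass filter.

    ``cutoff_norm`` is the cut-off as a fraction of the Nyquist frequency.
    Forward-backward application (``sosfiltfilt``) preserves onset and
    offset timing at the cost of squaring the magnitude response.
    """
    if mode not in ("highpass", "lowpass"):
        raise ParameterError("mode must be 'highpass' or 'lowpass'")
    if not 0 < cutoff_norm < 1:
        raise ParameterError("cutoff_norm must lie in (0, 1)")
    x = np.asarray(samples, dtype=float)
    sos = sps.butter(2, cutoff_norm, btype=mode, output="sos")
    # sosfiltfilt needs more than 3 * (number of taps) samples of context
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise ParameterError(
            f"input of {x.size} samples is shorter than the filter warm-up "
            f"({padlen + 1} samples)"
        )
    return sps.sosfiltfilt(sos, x)


def abs_derivative(samples: np.ndarray) -> np.ndarray:
    """Rectified first difference: ``out[i] = |x[i+1] - x[i]|``."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ParameterError("need at least 2 samples for a derivative")
    return np.abs(np.diff(x))


def moving_average(samples: np.ndarray, window_n: int) -> np.ndarray:
    """Trailing moving average.

    ``out[i]`` is the mean of ``x[i - window_n + 1 .. i]`` for
    ``i >= window_n - 1``; earlier indices are NaN (undefined) so that a
    threshold search can never trigger on a partially filled window.
    """
    x = np.asarray(samples, dtype=float)
    if window_n < 1:
        raise ParameterError("window_n must be >= 1")
    if x.size < window_n:
        raise ParameterError("input shorter than the averaging window")
    out = np.full(x.size, np.nan)
    csum = np.cumsum(np.concatenate(([0.0], x)))
    out[window_n - 1 :] = (csum[window_n:] - csum[: x.size - window_n + 1]) / window_n
    return out


def spectrogram(samples: np.ndarray, n_segments: int, fs: float = 1.0):
    """Hamming-window spectrogram with 50 % segment overlap.

    The frame is divided into ``n_segments`` segments of length
    ``floor(2 * len / (n_segments + 1))`` hopping by half a segment, each
    Hamming-windowed.  Returns ``(freqs, times, psd, summed_power)`` where
    ``psd`` is the per-segment power spectral density (freq x segment) and
    ``summed_power`` is its across-frequency sum per segment — the
    quantity displayed when choosing an MEP template.
    """
    x = np.asarray(samples, dtype=float)
    if n_segments < 2:
        raise ParameterError("n_segments must be >= 2")
    seg_len = (2 * x.size) // (n_segments + 1)
    if seg_len < 8:
        raise ParameterError("frame too short for the requested segmentation")
    hop = seg_len // 2
    freqs, times, psd = sps.spectrogram(
        x,
        fs=fs,
        window="hamming",
        nperseg=seg_len,
        noverlap=seg_len - hop,
        mode="psd",
        detrend=False,
    )
    return freqs, times, psd, psd.sum(axis=0)


def _strict_local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; a flat minimum takes its first index."""
    _, props = sps.find_peaks(-x, plateau_size=1)
    return props["left_edges"]


def prepulse_stats(
    trial: EMGTrial,
    artifact_idx: int,
    config: AnalysisConfig = AnalysisConfig(),
    prev_frame_end: Optional[int] = None,
) -> PrePulseStats:
    """Baseline statistics from the pre-pulse voluntary EMG.

    The segment runs from the end of the previous frame of interest (or
    the start of the recording for the first trial) up to the artifact,
    excluding the final ``prepulse_guard_ms`` before the pulse.  With
    ``config.prepulse_max_ms`` set, the segment is additionally capped to
    that many ms before the artifact.

    ``mean_negative_peak`` is the mean amplitude of all strict local
    minima with negative value; ``mean_abs_derivative_hp`` is the mean
    rectified first difference of the high-pass filtered segment.
    """
    fs = trial.sampling_rate
    guard = ms_to_samples(config.prepulse_guard_ms, fs)
    end = artifact_idx - guard
    start = int(prev_frame_end) if prev_frame_end is not None else 0
    if config.prepulse_max_ms is not None:
        start = max(start, end - ms_to_samples(config.prepulse_max_ms, fs))
    if end - start < ms_to_samples(40.0, fs):
        raise DetectionError(
            "less than 40 ms of pre-pulse data available", stage="prepulse"
        )
    segment = trial.samples[start:end]
    minima = _strict_local_minima(segment)
    values = segment[minima]
    values = values[values < 0]
    if values.size == 0:
        raise DetectionError(
            "no negative peaks in the pre-pulse segment; review the trial "
            "manually",
            stage="prepulse",
        )
    hp = butterworth_filter(segment, config.cutoff_norm, "highpass")
    return PrePulseStats(
        mean_negative_peak=float(values.mean()),
        mean_abs_derivative_hp=float(abs_derivative(hp).mean()),
        n_peaks=int(values.size),
        segment=(start, end),
    )
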