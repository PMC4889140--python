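"""Analysis configuration.

Every numeric threshold and window of the detection pipeline lives in
:class:`AnalysisConfig`, with defaults matching the published automated
CSP procedure at 5 kHz sampling.  Configs serialize to/from plain JSON so
an analysis run can log the exact parameter set it used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import ParameterError

#: Valid MEP-duration methods.
MEP_METHODS = ("matched_filter", "lowpass_peak", "fixed")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows of the CSP detection pipeline.

    Attributes
    ----------
    pre_ms, post_ms : float
        Frame of interest: ``pre_ms`` before the TMS artifact to
        ``post_ms`` after it.
    mep_min_search_ms : (float, float)
        Window after the artifact searched for the MEP minimum.
    cutoff_norm : float
        Normalized filter cut-off as a fraction of Nyquist (MATLAB
        convention); 0.016 is 40 Hz at 5 kHz sampling.
    moving_avg_n : int
        Length (samples) of the trailing moving average applied to the
        rectified derivative in the CSP-offset search.
    offset_threshold_fraction : float
        The CSP offset is the first moving-average point exceeding this
        fraction of the mean absolute derivative of the pre-pulse EMG.
    offset_search_ms : (float, float)
        Search window for the CSP offset, relative to the MEP offset.
    similarity_threshold : float
        Minimum normalized-correlation similarity for a matched-filter
        event (0-1).
    plausibility_margin_ms : float
        A detected CSP duration must exceed the MEP duration by more than
        this margin, otherwise the trial is flagged implausible.
    mep_method : str
        One of :data:`MEP_METHODS`.
    fixed_mep_ms : float
        MEP duration assumed by the ``fixed`` method.
    lowpass_peak_min_mv : float
        Minimum absolute amplitude for peaks of the low-pass filtered
        signal in the ``lowpass_peak`` method.
    prepulse_guard_ms : float
        Pre-pulse data this close to the artifact is excluded from the
        baseline statistics (stimulus-artifact leakage guard).
    prepulse_max_ms : float or None
        If set, cap the pre-pulse baseline segment to this many ms before
        the artifact; ``None`` uses all available pre-pulse data.
    spectrogram_segments : int
        Number of 50 %-overlap Hamming segments used by the spectrogram
        view of a frame.
    """

    pre_ms: float = 60.0
    post_ms: float = 420.0
    mep_min_search_ms: Tuple[float, float] = (5.0, 45.0)
    cutoff_norm: float = 0.016
    moving_avg_n: int = 30
    offset_threshold_fraction: float = 0.75
    offset_search_ms: Tuple[float, float] = (10.0, 400.0)
    similarity_threshold: float = 0.95
    plausibility_margin_ms: float = 5.0
    mep_method: str = "matched_filter"
    fixed_mep_ms: float = 25.0
    lowpass_peak_min_mv: float = 2.0
    prepulse_guard_ms: float = 2.0
    prepulse_max_ms: Optional[float] = None
    spectrogram_segments: int = 20

    def __post_init__(self):
        if self.pre_ms <= 0 or self.post_ms <= 0:
            raise ParameterError("frame windows must be positive")
        lo, hi = self.mep_min_search_ms
        if not 0 <= lo < hi:
            raise ParameterError("mep_min_search_ms must be an increasing window")
        if not 0 < self.cutoff_norm < 1:
            raise ParameterError("cutoff_norm must lie in (0, 1)")
        if self.moving_avg_n < 1:
            raise ParameterError("moving_avg_n must be >= 1")
        if not 0 < self.offset_threshold_fraction < 1:
            raise ParameterError("offset_threshold_fraction must lie in (0, 1)")
        lo, hi = self.offset_search_ms
        if not 0 <= lo < hi:
            raise ParameterError("offset_search_ms must be an increasing window")
        if not 0 < self.similarity_threshold <= 1:
            raise ParameterError("similarity_threshold must lie in (0, 1]")
        if self.plausibility_margin_ms < 0:
            raise ParameterError("plausibility_margin_ms must be >= 0")
        if self.mep_method not in MEP_METHODS:
            raise ParameterError(f"mep_method must be one of {MEP_METHODS}")
        if self.fixed_mep_ms <= 0:
            raise ParameterError("fixed_mep_ms must be positive")
        if self.spectrogram_segments < 2:
            raise ParameterError("spectrogram_segments must be >= 2")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mep_min_search_ms"] = list(self.mep_min_search_ms)
        d["offset_search_ms"] = list(self.offset_search_ms)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for key in ("mep_min_search_ms", "offset_search_ms"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert a duration in milliseconds to a whole number of samples."""
    return int(round(ms * fs / 1000.0))


def samples_to_ms(n: int, fs: float) -> float:
    """Convert a sample count (or index difference) to milliseconds."""
    return n / fs * 1000.0
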