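"""Silent-period onset/offset rules and the per-trial pipeline.

CSP onset
    Starting from the MEP minimum and scanning backward in time toward
    the artifact, the onset is the first sample whose value exceeds the
    mean negative-peak amplitude of the pre-pulse EMG.  This index is at
    once the CSP onset and the MEP onset: the reported silent period
    includes the preceding MEP, the convention recommended by the IFCN
    committee.

CSP offset
    Within a 10-400 ms window after the MEP offset, the offset is the
    first point where the 30-sample trailing moving average of the
    rectified derivative of the high-pass filtered signal exceeds 75 % of
    the corresponding pre-pulse mean — the return of continuous voluntary
    EMG activity.

Plausibility gate
    Detected durations not exceeding the MEP duration by more than 5 ms
    are flagged implausible; stage failures are flagged instead of
    raised, so no trial is ever silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ms_to_samples, samples_to_ms
from .errors import DetectionError
from .mep import MEPResult, MEPTemplate, detect_mep, find_mep_minimum
from .signal_prep import (
    EMGTrial,
    FrameOfInterest,
    PrePulseStats,
    abs_derivative,
    butterworth_filter,
    extract_frame,
    locate_tms_artifact,
    moving_average,
    prepulse_stats,
)

FLAG_OK = "ok"
FLAG_IMPLAUSIBLE = "implausible"
FLAG_FAILED = "detection_failed"


@dataclass
class TrialResult:
    """Outcome of analysing one trial (absolute sample indices)."""

    trial_id: str
    artifact_idx: Optional[int] = None
    mep: Optional[MEPResult] = None
    csp_onset_idx: Optional[int] = None
    csp_offset_idx: Optional[int] = None
    csp_duration_ms: Optional[float] = None
    flag: str = FLAG_OK
    notes: str = ""

    def to_row(self, fs: float) -> Dict:
        """Flatten to the results-CSV schema (times in ms from trial start)."""

        def ms(idx):
            return None if idx is None else samples_to_ms(idx, fs)

        return dict(
            trial_id=self.trial_id,
            artifact_ms=ms(self.artifact_idx),
            mep_onset_ms=ms(self.mep.onset_idx if self.mep else None),
            mep_offset_ms=ms(self.mep.offset_idx if self.mep else None),
            mep_duration_ms=self.mep.duration_ms if self.mep else None,
            csp_offset_ms=ms(self.csp_offset_idx),
            csp_duration_ms=self.csp_duration_ms,
            flag=self.flag,
            notes=self.notes,
        )


def detect_csp_onset(
    frame: FrameOfInterest, mep_min_idx: int, pstats: PrePulseStats
) -> int:
    """Backward scan from the MEP minimum for the first supra-baseline sample.

    Returns the absolute index of the first sample (moving backward from
    ``mep_min_idx - 1`` toward the artifact) whose value is strictly
    greater than the pre-pulse mean negative-peak amplitude.
    """
    rel_min = mep_min_idx - frame.start_idx
    if not 0 <= rel_min < frame.samples.size:
        raise DetectionError("MEP minimum outside the frame", stage="csp_onset")
    seg = frame.samples[frame.artifact_offset : rel_min]
    above = np.flatnonzero(seg > pstats.mean_negative_peak)
    if above.size == 0:
        raise DetectionError(
            "no sample above the pre-pulse negative-peak baseline between "
            "artifact and MEP minimum",
            stage="csp_onset",
        )
    return frame.start_idx + frame.artifact_offset + int(above[-1])


def detect_csp_offset(
    frame: FrameOfInterest,
    mep_offset_idx: int,
    pstats: PrePulseStats,
    config: AnalysisConfig = AnalysisConfig(),
) -> int:
    """First moving-average exceedance of the pre-pulse derivative baseline.

    The search window is ``offset_search_ms`` after the MEP offset,
    clipped to the frame (with a warning).  The rectified derivative of
    the high-pass filtered frame is averaged over a trailing
    ``moving_avg_n``-sample window — only fully populated windows inside
    the search region may trigger — and the offset is the first index
    where this average strictly exceeds ``offset_threshold_fraction``
    times the pre-pulse mean absolute derivative.
    """
    fs = frame.sampling_rate
    lo_ms, hi_ms = config.offset_search_ms
    w0 = mep_offset_idx + ms_to_samples(lo_ms, fs)
    w1 = mep_offset_idx + ms_to_samples(hi_ms, fs)
    if w1 > frame.end_idx:
        warnings.warn(
            "CSP-offset search window clipped at the end of the frame",
            stacklevel=2,
        )
        w1 = frame.end_idx
    if w0 >= frame.end_idx:
        raise DetectionError(
            "no room for a CSP-offset search window after the MEP offset",
            stage="csp_offset",
        )
    hp = butterworth_filter(frame.samples, config.cutoff_norm, "highpass")
    deriv = abs_derivative(hp)
    a = w0 - frame.start_idx
    b = min(w1 - frame.start_idx, deriv.size)
    if b - a < config.moving_avg_n:
        raise DetectionError(
            "CSP-offset search window shorter than the moving-average window",
            stage="csp_offset",
        )
    ma = moving_average(deriv[a:b], config.moving_avg_n)
    threshold = config.offset_threshold_fraction * pstats.mean_abs_derivative_hp
    crossing = np.flatnonzero(ma > threshold)  # NaN head compares False
    if crossing.size == 0:
        raise DetectionError(
            "voluntary EMG did not return within the CSP-offset search window",
            stage="csp_offset",
        )
    return w0 + int(crossing[0])


def analyze_trial(
    trial: EMGTrial,
    config: AnalysisConfig = AnalysisConfig(),
    template: Optional[MEPTemplate] = None,
    prev_frame_end: Optional[int] = None,
) -> TrialResult:
    """Run the full detection pipeline on one trial.

    Stage order: artifact localization, frame extraction, pre-pulse
    statistics, MEP minimum, CSP onset (= MEP onset), MEP offset, CSP
    offset, plausibility gate.  Every stage failure yields a flagged
    result (``detection_failed`` with the stage recorded in the notes)
    rather than an exception, so flagged trials can be exported for
    offline review instead of being dropped.
    """
    result = TrialResult(trial_id=trial.trial_id)
    try:
        artifact_idx = locate_tms_artifact(trial)
        result.artifact_idx = artifact_idx
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frame = extract_frame(trial, artifact_idx, config)
            pstats = prepulse_stats(
                trial, artifact_idx, config, prev_frame_end=prev_frame_end
            )
            min_idx = find_mep_minimum(frame, config)
            onset_idx = detect_csp_onset(frame, min_idx, pstats)
            mep = detect_mep(frame, onset_idx, min_idx, config, template)
            result.mep = mep
            result.csp_onset_idx = onset_idx
            offset_idx = detect_csp_offset(frame, mep.offset_idx, pstats, config)
    except DetectionError as err:
        result.flag = FLAG_FAILED
        result.notes = f"{err.stage or 'detection'}: {err}"
        return result
    result.csp_offset_idx = offset_idx
    result.csp_duration_ms = samples_to_ms(offset_idx - onset_idx, trial.sampling_rate)
    if result.csp_duration_ms <= mep.duration_ms + config.plausibility_margin_ms:
        result.flag = FLAG_IMPLAUSIBLE
        result.notes = (
            f"csp duration {result.csp_duration_ms:.1f} ms <= mep duration "
            f"{mep.duration_ms:.1f} ms + {config.plausibility_margin_ms:.0f} ms"
        )
    return result


@dataclass
class DatasetSummary:
    """Per-dataset counts and duration statistics of unflagged trials."""

    n_trials: int
    n_ok: int
    n_implausible: int
    n_failed: int
    mean_csp_ms: Optional[float]
    sd_csp_ms: Optional[float]
    flagged_ids: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return dict(
            n_trials=self.n_trials,
            n_ok=self.n_ok,
            n_implausible=self.n_implausible,
            n_failed=self.n_failed,
            mean_csp_ms=self.mean_csp_ms,
            sd_csp_ms=self.sd_csp_ms,
            flagged_ids=list(self.flagged_ids),
        )


def analyze_dataset(
    trials: List[EMGTrial],
    config: AnalysisConfig = AnalysisConfig(),
    template: Optional[MEPTemplate] = None,
) -> Tuple[pd.DataFrame, List[TrialResult], DatasetSummary]:
    """Analyze every trial; return (results table, flagged results, summary)."""
    if not trials:
        raise DetectionError("empty dataset", stage="dataset")
    results = [analyze_trial(t, config, template) for t in trials]
    return summarize_results(results, trials[0].sampling_rate)


def summarize_results(
    results: List[TrialResult], fs: float
) -> Tuple[pd.DataFrame, List[TrialResult], DatasetSummary]:
    """Tabulate per-trial results and compute the dataset summary."""
    table = pd.DataFrame([r.to_row(fs) for r in results])
    flagged = [r for r in results if r.flag != FLAG_OK]
    ok = table[table["flag"] == FLAG_OK]["csp_duration_ms"]
    summary = DatasetSummary(
        n_trials=len(results),
        n_ok=int((table["flag"] == FLAG_OK).sum()),
        n_implausible=int((table["flag"] == FLAG_IMPLAUSIBLE).sum()),
        n_failed=int((table["flag"] == FLAG_FAILED).sum()),
        mean_csp_ms=float(ok.mean()) if len(ok) else None,
        sd_csp_ms=float(ok.std(ddof=1)) if len(ok) > 1 else None,
        flagged_ids=[r.trial_id for r in flagged],
    )
    return table, flagged, summary
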