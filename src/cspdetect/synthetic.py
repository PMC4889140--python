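"""Seeded generator of TMS-EMG trials with known ground truth.

Each trial emulates a single-pulse TMS recording during tonic contraction
at roughly 20 % of maximum voluntary contraction: band-limited Gaussian
background EMG, a narrow high-amplitude stimulus artifact, a motor evoked
potential (MEP) of a few mV some 20 ms after the pulse, and a silent
period during which the voluntary background is multiplicatively
suppressed before ramping back to its tonic level.  The construction
indices are returned as :class:`GroundTruth` so detector recovery can be
scored without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ms_to_samples, samples_to_ms
from .errors import ParameterError
from .signal_prep import EMGTrial, butterworth_filter

#: Corruption modes understood by :func:`generate_dataset`. ``no_mep``
#: emulates a failure to evoke an MEP: the pulse fires but voluntary EMG
#: simply continues, so neither MEP nor silent period is present.
#: ``no_csp`` keeps the MEP but omits the silent period — a stress mode:
#: the plausibility gate is structurally blind to it (the offset search
#: starts 10 ms after the MEP offset, so a detected duration always
#: exceeds the MEP + 5 ms cut-off) and it is not part of the default mix.
CORRUPTION_KINDS = ("no_mep", "no_csp")
DEFAULT_CORRUPTION = ("no_mep",)

MEP_SHAPES = ("monophasic_negative", "biphasic")


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of the synthetic trial generator.

    Times are ms, amplitudes mV.  ``background_rms`` is the tonic
    contraction level; ``residual_fraction`` is the background amplitude
    during the silent period relative to tonic; ``return_ramp`` is the
    time over which the background RMS ramps linearly from the residual
    level back to full after the silent period ends.
    """

    sampling_rate: float = 5000.0
    trial_duration: float = 600.0
    artifact_time: float = 100.0
    background_rms: float = 0.15
    background_band: Tuple[float, float] = (20.0, 450.0)
    artifact_amplitude: float = 8.0
    artifact_width: float = 1.0
    mep_latency: float = 20.0
    mep_duration: float = 25.0
    mep_peak_amplitude: float = 3.0
    mep_shape: str = "monophasic_negative"
    csp_duration: float = 150.0
    return_ramp: float = 20.0
    residual_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.trial_duration <= 0:
            raise ParameterError("sampling_rate and trial_duration must be positive")
        lo, hi = self.background_band
        if not 0 < lo < hi:
            raise ParameterError("background_band must be an increasing pass band")
        if hi >= self.sampling_rate / 2:
            raise ParameterError("background_band upper edge must be below Nyquist")
        if self.background_rms < 0:
            raise ParameterError("background_rms must be >= 0")
        if self.mep_shape not in MEP_SHAPES:
            raise ParameterError(f"mep_shape must be one of {MEP_SHAPES}")
        if self.csp_duration <= self.mep_duration:
            raise ParameterError("csp_duration must exceed mep_duration")
        if self.csp_duration <= self.mep_duration + self.return_ramp:
            raise ParameterError(
                "csp_duration must exceed mep_duration + return_ramp (the "
                "resumption ramp completes at the CSP offset)"
            )
        if not 0 <= self.residual_fraction < 1:
            raise ParameterError("residual_fraction must lie in [0, 1)")
        total = (
            self.artifact_time
            + self.mep_latency
            + self.csp_duration
            + self.return_ramp
        )
        if total >= self.trial_duration:
            raise ParameterError(
                "artifact_time + mep_latency + csp_duration + return_ramp must "
                "fit inside trial_duration"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Construction indices of one clean synthetic trial.

    The CSP onset equals the MEP onset (the measured silent period
    includes the preceding MEP), so ``csp_duration_ms`` spans
    ``mep_onset_idx`` to ``csp_offset_idx``.  Following the SP2
    convention — the silent period ends at the reversion to *continuous*
    voluntary EMG activity — ``csp_offset_idx`` marks the completion of
    the resumption ramp, not the first flicker of returning activity.
    """

    mep_onset_idx: int
    mep_min_idx: int
    mep_offset_idx: int
    csp_offset_idx: int
    csp_duration_ms: float


def generate_background(
    duration_ms: float, params: GenerationParams, seed: Optional[int] = None
) -> np.ndarray:
    """Band-limited Gaussian background EMG with exact RMS.

    White Gaussian noise is band-pass filtered (zero phase) to
    ``params.background_band`` and rescaled so its RMS equals
    ``params.background_rms`` exactly.  ``background_rms = 0`` yields an
    all-zero array.
    """
    if duration_ms <= 0:
        raise ParameterError("duration_ms must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = ms_to_samples(duration_ms, params.sampling_rate)
    return _background(n, params, rng)


def _background(n: int, params: GenerationParams, rng: np.random.Generator):
    if params.background_rms == 0:
        return np.zeros(n)
    nyq = params.sampling_rate / 2
    lo, hi = params.background_band
    white = rng.standard_normal(n)
    from scipy import signal as sps

    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x * (params.background_rms / rms)


def _mep_waveform(n: int, amplitude: float, shape: str) -> Tuple[np.ndarray, int]:
    """MEP waveform of ``n`` samples; returns (waveform, argmin)."""
    tau = np.arange(n) / n
    w = np.zeros(n)
    if shape == "monophasic_negative":
        # descent to a single minimum at 30 % of the duration, recovery,
        # then a small positive rebound
        neg = tau < 0.6
        w[neg] = -amplitude * np.sin(np.pi * tau[neg] / 0.6)
        w[~neg] = 0.25 * amplitude * np.sin(np.pi * (tau[~neg] - 0.6) / 0.4)
    else:  # biphasic: positive lobe, deep trough, small rebound
        first = tau < 0.4
        mid = (tau >= 0.4) & (tau < 0.8)
        last = tau >= 0.8
        w[first] = 0.5 * amplitude * np.sin(np.pi * tau[first] / 0.4)
        w[mid] = -amplitude * np.sin(np.pi * (tau[mid] - 0.4) / 0.4)
        w[last] = 0.2 * amplitude * np.sin(np.pi * (tau[last] - 0.8) / 0.2)
    return w, int(np.argmin(w))


def _artifact_waveform(n_half: int, amplitude: float) -> np.ndarray:
    """Raised-cosine stimulus transient spanning ``2 * n_half + 1`` samples."""
    m = 2 * n_half + 1
    return amplitude * np.hanning(m + 2)[1:-1]


def generate_trial(
    params: GenerationParams,
    rng: Optional[np.random.Generator] = None,
    *,
    insert_mep: bool = True,
    insert_silent_period: bool = True,
    trial_id: str = "trial",
) -> Tuple[EMGTrial, Optional[GroundTruth]]:
    """Generate one trial and its ground truth.

    The trial is background EMG plus an artifact spike at
    ``artifact_time``, an MEP starting ``mep_latency`` after the artifact,
    and multiplicative suppression of the background to
    ``residual_fraction`` from the MEP offset until ``return_ramp`` ms
    before the CSP offset, where a linear amplitude ramp restores the
    tonic level; voluntary activity is continuous again exactly at the
    ground-truth CSP offset.  ``insert_mep=False`` /
    ``insert_silent_period=False`` produce corrupted trials (and ``None``
    ground truth unless both components are present).

    The ground-truth MEP minimum is the argmin of the *composite* signal
    within the MEP span, so noise cannot make an honest detector disagree
    with the truth by construction.
    """
    fs = params.sampling_rate
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = ms_to_samples(params.trial_duration, fs)
    x = _background(n, params, rng)

    a_idx = ms_to_samples(params.artifact_time, fs)
    onset = a_idx + ms_to_samples(params.mep_latency, fs)
    mep_n = ms_to_samples(params.mep_duration, fs)
    offset = onset + mep_n
    csp_off = onset + ms_to_samples(params.csp_duration, fs)
    ramp_n = ms_to_samples(params.return_ramp, fs)

    if insert_silent_period:
        env = np.ones(n)
        ramp_start = csp_off - ramp_n
        env[offset:ramp_start] = params.residual_fraction
        if ramp_n > 0:
            env[ramp_start:csp_off] = np.linspace(
                params.residual_fraction, 1.0, ramp_n, endpoint=False
            )
        x *= env

    if insert_mep:
        w, w_min = _mep_waveform(mep_n, params.mep_peak_amplitude, params.mep_shape)
        x[onset:offset] += w

    half = max(1, ms_to_samples(params.artifact_width / 2, fs))
    art = _artifact_waveform(half, params.artifact_amplitude)
    lo = a_idx - half
    x[lo : lo + art.size] += art

    trial = EMGTrial(
        samples=x, sampling_rate=fs, trigger_idx=a_idx, trial_id=trial_id
    )
    if not (insert_mep and insert_silent_period):
        return trial, None
    min_idx = onset + int(np.argmin(x[onset:offset]))
    truth = GroundTruth(
        mep_onset_idx=onset,
        mep_min_idx=min_idx,
        mep_offset_idx=offset,
        csp_offset_idx=csp_off,
        csp_duration_ms=samples_to_ms(csp_off - onset, fs),
    )
    return trial, truth


# jitter applied per trial by generate_dataset: Gaussian on latency (SD 1 ms),
# log-normal on amplitudes (sigma 0.1), Gaussian on csp_duration (SD 10 ms),
# truncated so the construction invariants always hold
LATENCY_JITTER_SD_MS = 1.0
AMPLITUDE_JITTER_SIGMA = 0.1
CSP_JITTER_SD_MS = 10.0


def _jittered(params: GenerationParams, rng, csp_range=None) -> GenerationParams:
    latency = float(
        np.clip(
            rng.normal(params.mep_latency, LATENCY_JITTER_SD_MS),
            0.5 * params.mep_latency,
            1.5 * params.mep_latency,
        )
    )
    amp = float(params.mep_peak_amplitude * rng.lognormal(0.0, AMPLITUDE_JITTER_SIGMA))
    art_amp = float(
        params.artifact_amplitude * rng.lognormal(0.0, AMPLITUDE_JITTER_SIGMA)
    )
    if csp_range is not None:
        csp = float(rng.uniform(*csp_range))
    else:
        csp = float(rng.normal(params.csp_duration, CSP_JITTER_SD_MS))
    max_csp = (
        params.trial_duration
        - params.artifact_time
        - latency
        - params.return_ramp
        - 1.0
    )
    csp = float(
        np.clip(csp, params.mep_duration + params.return_ramp + 10.0, max_csp)
    )
    return dataclasses.replace(
        params,
        mep_latency=latency,
        mep_peak_amplitude=amp,
        artifact_amplitude=art_amp,
        csp_duration=csp,
    )


def generate_dataset(
    n_trials: int,
    params: GenerationParams = GenerationParams(),
    seed: int = 0,
    artifact_trial_fraction: float = 0.0,
    csp_duration_range: Optional[Tuple[float, float]] = None,
    corruption_kinds: Tuple[str, ...] = DEFAULT_CORRUPTION,
) -> Tuple[List[EMGTrial], pd.DataFrame]:
    """Generate a jittered multi-trial dataset with a truth table.

    ``round(artifact_trial_fraction * n_trials)`` trials are corrupted,
    cycling through ``corruption_kinds`` (default: failure-to-evoke only,
    see :data:`CORRUPTION_KINDS`), and marked in the truth table.  Clean
    trials receive per-trial jitter on MEP latency, amplitudes and CSP
    duration; ``csp_duration_range`` draws the CSP duration uniformly
    from that range instead (the layout used by the parameter-recovery
    validation).  Bitwise reproducible per seed.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if not 0 <= artifact_trial_fraction <= 1:
        raise ParameterError("artifact_trial_fraction must lie in [0, 1]")
    if any(k not in CORRUPTION_KINDS for k in corruption_kinds):
        raise ParameterError(f"corruption kinds must be among {CORRUPTION_KINDS}")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_bad = int(round(artifact_trial_fraction * n_trials))
    bad_idx = set(rng.choice(n_trials, size=n_bad, replace=False).tolist())

    trials: List[EMGTrial] = []
    rows = []
    child_seqs = ss.spawn(n_trials)
    kind_cycle = 0
    for i in range(n_trials):
        trial_rng = np.random.default_rng(child_seqs[i])
        trial_id = f"trial_{i:03d}"
        p_i = _jittered(params, trial_rng, csp_range=csp_duration_range)
        if i in bad_idx:
            kind = corruption_kinds[kind_cycle % len(corruption_kinds)]
            kind_cycle += 1
            trial, _ = generate_trial(
                p_i,
                trial_rng,
                insert_mep=(kind != "no_mep"),
                insert_silent_period=False,
                trial_id=trial_id,
            )
            truth_row = dict(
                trial_id=trial_id,
                corrupted=True,
                corruption=kind,
                mep_onset_idx=np.nan,
                mep_min_idx=np.nan,
                mep_offset_idx=np.nan,
                csp_offset_idx=np.nan,
                csp_duration_ms=np.nan,
            )
        else:
            trial, truth = generate_trial(p_i, trial_rng, trial_id=trial_id)
            truth_row = dict(
                trial_id=trial_id,
                corrupted=False,
                corruption="",
                mep_onset_idx=float(truth.mep_onset_idx),
                mep_min_idx=float(truth.mep_min_idx),
                mep_offset_idx=float(truth.mep_offset_idx),
                csp_offset_idx=float(truth.csp_offset_idx),
                csp_duration_ms=truth.csp_duration_ms,
            )
        truth_row.update(
            mep_latency_ms=p_i.mep_latency,
            mep_peak_amplitude_mv=p_i.mep_peak_amplitude,
            csp_duration_param_ms=p_i.csp_duration,
        )
        trials.append(trial)
        rows.append(truth_row)
    return trials, pd.DataFrame(rows)
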