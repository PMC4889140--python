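"""Dataset reading and writing.

A dataset on disk is a directory of single-column delimited-text trial
files (one sample per line, mV after unit conversion) plus a
``metadata.json`` sidecar::

    {
      "sampling_rate_hz": 5000,
      "units": "mV",
      "trials": [{"file": "trial_000.txt", "trial_id": "...",
                  "trigger_idx": 500}, ...],
      "truth": [...]          # optional, written by the simulator
    }

Results are written as a CSV (one row per trial, flagged trials always
included) with a JSON summary alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .csp import DatasetSummary, TrialResult
from .errors import ParameterError
from .mep import MEPTemplate
from .signal_prep import EMGTrial

#: multiplicative factors to mV
_UNIT_FACTORS = {
    "mv": 1.0,
    "millivolt": 1.0,
    "millivolts": 1.0,
    "uv": 1e-3,
    "µv": 1e-3,
    "μv": 1e-3,
    "microvolt": 1e-3,
    "microvolts": 1e-3,
    "v": 1e3,
    "volt": 1e3,
    "volts": 1e3,
}


@dataclass
class DatasetManifest:
    """Resolved description of a dataset directory."""

    root: Path
    sampling_rate: float
    units: str
    trial_files: List[Path] = field(default_factory=list)
    trigger_indices: List[Optional[int]] = field(default_factory=list)
    truth: Optional[pd.DataFrame] = None


def _unit_factor(units: str) -> float:
    try:
        return _UNIT_FACTORS[units.strip().lower()]
    except KeyError:
        raise ParameterError(f"cannot convert units {units!r} to mV") from None


def write_dataset(
    trials: List[EMGTrial],
    out_dir,
    truth: Optional[pd.DataFrame] = None,
    units: str = "mV",
) -> Path:
    """Write one text file per trial plus a JSON metadata/truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not trials:
        raise ParameterError("no trials to write")
    fs = trials[0].sampling_rate
    meta_trials = []
    for i, trial in enumerate(trials):
        if trial.sampling_rate != fs:
            raise ParameterError("all trials in a dataset must share one rate")
        fname = f"{trial.trial_id or f'trial_{i:03d}'}.txt"
        np.savetxt(out / fname, trial.samples, fmt="%.17g")
        meta_trials.append(
            dict(
                file=fname,
                trial_id=trial.trial_id or f"trial_{i:03d}",
                trigger_idx=trial.trigger_idx,
            )
        )
    meta = dict(sampling_rate_hz=fs, units=units, trials=meta_trials)
    if truth is not None:
        meta["truth"] = json.loads(truth.to_json(orient="records"))
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    return out


def load_dataset(path) -> Tuple[List[EMGTrial], DatasetManifest]:
    """Load a dataset directory (or a metadata.json path).

    Samples are normalized to mV using the declared units; the sampling
    rate is attached to every trial.  Trials come back in manifest order.
    """
    p = Path(path)
    meta_path = p if p.is_file() else p / "metadata.json"
    if not meta_path.exists():
        raise ParameterError(f"no metadata.json found at {p}")
    root = meta_path.parent
    with open(meta_path) as fh:
        meta = json.load(fh)
    if "sampling_rate_hz" not in meta:
        raise ParameterError("metadata is missing sampling_rate_hz")
    fs = float(meta["sampling_rate_hz"])
    factor = _unit_factor(meta.get("units", "mV"))
    manifest = DatasetManifest(
        root=root,
        sampling_rate=fs,
        units=meta.get("units", "mV"),
        truth=pd.DataFrame(meta["truth"]) if "truth" in meta else None,
    )
    trials = []
    for entry in meta.get("trials", []):
        fpath = root / entry["file"]
        if not fpath.exists():
            raise ParameterError(f"trial file {fpath} missing")
        samples = np.loadtxt(fpath, dtype=float) * factor
        trig = entry.get("trigger_idx")
        trials.append(
            EMGTrial(
                samples=np.atleast_1d(samples),
                sampling_rate=fs,
                trigger_idx=None if trig is None else int(trig),
                trial_id=entry.get("trial_id", fpath.stem),
            )
        )
        manifest.trial_files.append(fpath)
        manifest.trigger_indices.append(trig)
    if not trials:
        raise ParameterError("dataset contains no trials")
    return trials, manifest


def write_results(
    results: List[TrialResult],
    path,
    fs: float,
    summary: Optional[DatasetSummary] = None,
) -> Path:
    """Write the per-trial results CSV (+ JSON summary alongside).

    Flagged trials are written like any other row, with the flag and
    notes columns populated; overwriting an existing file is idempotent.
    """
    if not results:
        raise ParameterError("no results to write")
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([r.to_row(fs) for r in results])
    table.to_csv(out, index=False, float_format="%.6f")
    if summary is not None:
        with open(out.with_suffix(".summary.json"), "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
            fh.write("\n")
    return out


def write_template(template: MEPTemplate, path) -> Path:
    """Persist a template as text samples plus a JSON sidecar."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(out, template.samples, fmt="%.17g")
    sidecar = dict(
        fs=template.fs,
        source_trial_id=template.source_trial_id,
        n_samples=int(len(template)),
    )
    with open(out.with_suffix(out.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
    return out


def load_template(path) -> MEPTemplate:
    """Load a template written by :func:`write_template`."""
    p = Path(path)
    sidecar = p.with_suffix(p.suffix + ".json")
    if not sidecar.exists():
        raise ParameterError(f"template sidecar {sidecar} missing")
    with open(sidecar) as fh:
        meta = json.load(fh)
    samples = np.atleast_1d(np.loadtxt(p, dtype=float))
    return MEPTemplate(
        samples=samples,
        source_trial_id=meta.get("source_trial_id", ""),
        fs=float(meta["fs"]),
    )


def load_ratings(path) -> np.ndarray:
    """Read a ratings CSV as one value series.

    Accepts either a single-column file of values or a long-format file
    with ``subject,rater,value`` columns (values returned in subject
    order for a single rater file).
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "value" in cols:
        if "subject" in cols:
            df = df.sort_values(cols["subject"], kind="stable")
        return df[cols["value"]].to_numpy(dtype=float)
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(dtype=float)
    raise ParameterError(
        f"{path}: expected a single 'value' column or long-format "
        "subject,rater,value"
    )
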