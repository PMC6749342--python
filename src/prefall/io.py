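"""CSV/JSON interchange for trials and pipeline outputs.

A trial travels as a two-column CSV ``time_s,angle_rad`` plus an optional
JSON sidecar (same stem, ``.json``) carrying channel, perturbation metadata
and sampling rate.  Floats are written with ``%.17g`` so a write/read round
trip preserves values bit-for-bit, and file contents are deterministic
byte-for-byte for identical inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .synthetic import Trial
from .timeseries import TimeSeries

__all__ = [
    "TrialFormatError",
    "sidecar_path",
    "write_trial_csv",
    "read_trial_csv",
    "write_dataframe_csv",
]

log = logging.getLogger(__name__)

#: Maximum timestamp deviation from uniform sampling, seconds.
TIME_TOLERANCE_S = 1e-6


class TrialFormatError(ValueError):
    """Malformed trial CSV (missing columns, non-uniform timestamps...)."""


def sidecar_path(csv_path: Union[str, Path]) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_trial_csv(trial: Trial, path: Union[str, Path],
                    extra_meta: Optional[dict] = None) -> None:
    """Write a trial as CSV plus a JSON sidecar with its metadata."""
    path = Path(path)
    t = trial.signal.time()
    with open(path, "w", newline="") as f:
        f.write("time_s,angle_rad\n")
        for ti, vi in zip(t, trial.signal.values):
            f.write(f"{ti:.17g},{vi:.17g}\n")
    meta = {
        "channel": trial.channel,
        "perturbed": trial.perturbed,
        "onset_index": trial.onset_index,
        "fs_hz": trial.signal.fs_hz,
        "t0_s": trial.signal.t0_s,
        "trial_id": trial.trial_id,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(sidecar_path(path), "w") as f:
        json.dump(meta, f, indent=2, sort_keys=True)
        f.write("\n")


def read_trial_csv(path: Union[str, Path]) -> Trial:
    """Read a trial CSV (and its sidecar, if present).

    Without a sidecar the trial is assumed unperturbed with an empty channel
    label and a warning is logged.  Timestamps must be uniform to within
    ``TIME_TOLERANCE_S``; the first offending row is named in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_s", "angle_rad"} - set(df.columns)
    if missing:
        raise TrialFormatError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) < 2:
        raise TrialFormatError(f"{path}: need at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["angle_rad"].to_numpy(dtype=float)
    dt = (t[-1] - t[0]) / (len(t) - 1)
    if dt <= 0:
        raise TrialFormatError(f"{path}: non-increasing timestamps")
    expected = t[0] + dt * np.arange(len(t))
    dev = np.abs(t - expected)
    if np.any(dev > TIME_TOLERANCE_S):
        row = int(np.argmax(dev > TIME_TOLERANCE_S))
        raise TrialFormatError(
            f"{path}: non-uniform sampling at row {row + 1} "
            f"(time {t[row]:.6f} s deviates by {dev[row]:.2e} s)")

    side = sidecar_path(path)
    if side.exists():
        with open(side) as f:
            meta = json.load(f)
        fs = float(meta.get("fs_hz", 1.0 / dt))
        onset = meta.get("onset_index")
        trial = Trial(
            TimeSeries(v, fs, t0_s=float(meta.get("t0_s", t[0])),
                       channel=meta.get("channel", "")),
            onset_index=None if onset is None else int(onset),
            channel=meta.get("channel", ""),
            perturbed=bool(meta.get("perturbed", False)),
            trial_id=meta.get("trial_id", path.stem),
        )
    else:
        log.warning("%s: no sidecar found; assuming unperturbed trial", path)
        trial = Trial(TimeSeries(v, 1.0 / dt, t0_s=t[0]), onset_index=None,
                      channel="", perturbed=False, trial_id=path.stem)
    return trial


def write_dataframe_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Deterministic CSV export used for tuning tables and traces."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
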