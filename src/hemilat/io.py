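"""File formats: CSV readers/writers, configuration files, JSON reports.

Dialects are fixed: comma-separated, UTF-8, header row, "." decimal.

* Recording CSV: columns ``time_s, left_cmps, right_cmps``; the sampling
  rate is inferred from the time column.
* Schedule CSV: columns ``trial_index, onset_s, letter``.
* Cohort CSV: columns ``id, li_s1, li_s2, label_s1, label_s2`` and
  optionally ``subgroup``.
* Epoch output: long-format CSV ``trial_index, channel, rel_time_s,
  value, qc_status`` plus a JSON QC summary.
* Config files: JSON or YAML holding :class:`PreprocessConfig` fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import (BilateralRecording, EpochSet, PreprocessConfig,
                         PreprocessError, TaskSchedule)
from .reliability import PairedLISet

__all__ = [
    "read_recording_csv", "write_recording_csv",
    "read_schedule_csv", "write_schedule_csv",
    "read_cohort_csv", "write_cohort_csv",
    "write_epochs_csv", "write_json",
    "load_preprocess_config", "config_hash",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PreprocessError(f"{path}: missing required column(s) {missing}")


def read_recording_csv(path, expected_rate: float | None = None) -> BilateralRecording:
    """Load a two-channel recording; the sampling rate is inferred from
    the time column and, when given, validated against ``expected_rate``."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "left_cmps", "right_cmps"], path)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise PreprocessError(f"{path}: recording too short")
    dt = np.diff(t)
    if np.any(dt <= 0) or (dt.max() - dt.min()) > 1e-6:
        raise PreprocessError(f"{path}: time column is not uniformly sampled")
    rate = 1.0 / dt.mean()
    rate = float(round(rate, 6))
    if expected_rate is not None and abs(rate - expected_rate) > 1e-3:
        raise PreprocessError(
            f"{path}: sampling rate {rate} Hz does not match expected "
            f"{expected_rate} Hz")
    return BilateralRecording(rate, df["left_cmps"].to_numpy(float),
                              df["right_cmps"].to_numpy(float))


def write_recording_csv(rec: BilateralRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame({"time_s": t, "left_cmps": rec.left,
                       "right_cmps": rec.right})
    df.to_csv(path, index=False, float_format="%.6f")


def read_schedule_csv(path, **kwargs) -> TaskSchedule:
    """Load a trial schedule; trial timing durations can be overridden via
    keyword arguments (``instruction_dur``, ``task_dur``, ``rest_dur``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["trial_index", "onset_s", "letter"], path)
    df = df.sort_values("trial_index")
    return TaskSchedule(tuple(df["onset_s"].astype(float)),
                        letters=tuple(df["letter"].astype(str)), **kwargs)


def write_schedule_csv(sched: TaskSchedule, path) -> None:
    df = pd.DataFrame({
        "trial_index": np.arange(1, sched.n_trials + 1),
        "onset_s": sched.trial_onsets,
        "letter": sched.letters,
    })
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> PairedLISet:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "li_s1", "li_s2", "label_s1", "label_s2"], path)
    return PairedLISet.from_dataframe(df)


def write_cohort_csv(pairs: PairedLISet, path) -> None:
    pairs.to_dataframe().to_csv(path, index=False)


def write_epochs_csv(es: EpochSet, path, qc_json_path=None) -> None:
    """Long-format epoch export plus an optional JSON QC summary."""
    frames = []
    for e in es.epochs:
        for chan in ("left", "right"):
            frames.append(pd.DataFrame({
                "trial_index": e.trial_index,
                "channel": chan,
                "rel_time_s": es.rel_time,
                "value": getattr(e, chan),
                "qc_status": e.qc_status,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")
    if qc_json_path is not None:
        write_json(es.qc_summary(), qc_json_path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_preprocess_config(path=None) -> PreprocessConfig:
    """Build a :class:`PreprocessConfig` from a JSON or YAML file; a None
    path yields the defaults.  Unknown keys are rejected."""
    if path is None:
        return PreprocessConfig()
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise PreprocessError(f"{path}: config must be a mapping")
    valid = {f.name for f in dataclasses.fields(PreprocessConfig)}
    unknown = set(data) - valid
    if unknown:
        raise PreprocessError(f"{path}: unknown config key(s) {sorted(unknown)}")
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return PreprocessConfig(**data)


def config_hash(cfg) -> str:
    """Stable short hash of a dataclass config, for report provenance."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
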