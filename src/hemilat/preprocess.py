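"""Preprocessing of bilateral cerebral blood-flow-velocity (CBFV) recordings.

Functional transcranial Doppler sonography (fTCD) measures blood flow
velocity in the left and right middle cerebral arteries while a participant
performs a lateralized cognitive task (here: covert letter verbal fluency).
This module turns a raw two-channel velocity recording plus the task
schedule into a quality-controlled set of task-locked epochs:

    downsample -> epoch -> detect_artifacts -> normalize
              -> heart_cycle_integrate -> baseline_correct
              -> reject_out_of_range

Epochs span 10 s before the instruction screen until 5 s after the end of
the 20 s word-generation phase (38 s total at the defaults).  Velocities
are expressed per hemisphere as a percentage of that channel's session
mean, cardiac pulsatility is removed by per-cycle integration, and the 8 s
of rest preceding each instruction screen serves as the epoch baseline.
All downstream laterality statistics operate on the resulting
baseline-corrected Delta-% values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BilateralRecording",
    "TaskSchedule",
    "PreprocessConfig",
    "Epoch",
    "EpochSet",
    "PreprocessError",
    "InsufficientEpochsError",
    "DEFAULT_LETTERS",
    "downsample",
    "epoch",
    "detect_artifacts",
    "normalize",
    "heart_cycle_integrate",
    "baseline_correct",
    "reject_out_of_range",
    "manual_exclude",
    "preprocess_session",
]

#: Task letters of the standard 16-trial letter verbal fluency protocol.
DEFAULT_LETTERS = ("S", "B", "K", "V", "P", "A", "O", "T",
                   "G", "R", "M", "D", "H", "L", "W", "Z")

KEPT = "kept"
EXCLUDED_ARTIFACT = "excluded_artifact"
EXCLUDED_RANGE = "excluded_range"
EXCLUDED_MANUAL = "excluded_manual"

#: Minimum inter-beat interval in seconds used when delimiting cardiac
#: cycles (0.33 s corresponds to a ceiling of ~180 bpm).
MIN_INTERBEAT_S = 0.33


class PreprocessError(ValueError):
    """Raised when an input violates a preprocessing precondition."""


class InsufficientEpochsError(PreprocessError):
    """Raised when too few epochs survive quality control."""


@dataclass(frozen=True)
class BilateralRecording:
    """Synchronized left/right CBFV time series.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), positive.
    left, right : ndarray
        Velocity series in cm/s for the left and right artery.  Must have
        equal length.
    """

    sampling_rate: float
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise PreprocessError("sampling_rate must be positive")
        object.__setattr__(self, "left", np.asarray(self.left, dtype=float))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=float))
        if self.left.ndim != 1 or self.right.ndim != 1:
            raise PreprocessError("channels must be 1-D arrays")
        if len(self.left) != len(self.right):
            raise PreprocessError("left and right channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    def swapped(self) -> "BilateralRecording":
        """Return a copy with the hemispheres exchanged."""
        return BilateralRecording(self.sampling_rate, self.right.copy(), self.left.copy())


@dataclass(frozen=True)
class TaskSchedule:
    """Timing of the word-generation trials.

    ``trial_onsets`` are the onsets (s) of the instruction screens; each
    trial consists of ``instruction_dur`` s of instruction followed by
    ``task_dur`` s of word generation and ``rest_dur`` s of rest.
    """

    trial_onsets: tuple
    instruction_dur: float = 3.0
    task_dur: float = 20.0
    rest_dur: float = 15.0
    letters: tuple = DEFAULT_LETTERS

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.trial_onsets)
        object.__setattr__(self, "trial_onsets", onsets)
        object.__setattr__(self, "letters", tuple(self.letters))
        if len(onsets) == 0:
            raise PreprocessError("schedule has no trials")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise PreprocessError("trial onsets must be strictly increasing")
        min_gap = self.instruction_dur + self.task_dur
        if any(b - a < min_gap for a, b in zip(onsets, onsets[1:])):
            raise PreprocessError(
                f"inter-onset gaps must be >= instruction+task duration ({min_gap} s)")
        if len(self.letters) != len(onsets):
            raise PreprocessError("number of letters must match number of onsets")

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    All windows are in seconds relative to the instruction-screen onset.
    ``poi_window`` is the period of interest over which the laterality
    index is averaged: from 3 s after word-generation onset until the end
    of the task (17 s at the defaults).
    """

    target_rate: float = 25.0
    epoch_window: tuple = (-10.0, 28.0)
    quantile_bounds: tuple = (0.0001, 0.9999)
    range_bounds: tuple = (60.0, 140.0)
    baseline_window: tuple = (-8.0, 0.0)
    poi_window: tuple = (6.0, 23.0)

    def __post_init__(self) -> None:
        pre, post = self.epoch_window
        if not (pre < 0.0 < post):
            raise PreprocessError("epoch_window must straddle the instruction onset")
        for name in ("baseline_window", "poi_window"):
            lo, hi = getattr(self, name)
            if not (pre <= lo < hi <= post):
                raise PreprocessError(f"{name} must lie inside epoch_window")
        qlo, qhi = self.quantile_bounds
        if not (0.0 <= qlo < qhi <= 1.0):
            raise PreprocessError("quantile_bounds must satisfy 0 <= lo < hi <= 1")


@dataclass
class Epoch:
    """One trial's two-channel window on the common relative time grid."""

    trial_index: int  # 1-based position in the task design
    letter: str
    left: np.ndarray
    right: np.ndarray
    qc_status: str = KEPT
    hci_warn: bool = False  # set when cardiac-cycle integration found <2 troughs
    # snapshot of normalized (pre-baseline-subtraction) values, retained by
    # baseline_correct for the 60-140 % range-rejection test
    left_norm: np.ndarray | None = None
    right_norm: np.ndarray | None = None

    @property
    def kept(self) -> bool:
        return self.qc_status == KEPT

    def copy(self) -> "Epoch":
        return Epoch(
            self.trial_index, self.letter, self.left.copy(), self.right.copy(),
            self.qc_status, self.hci_warn,
            None if self.left_norm is None else self.left_norm.copy(),
            None if self.right_norm is None else self.right_norm.copy(),
        )


@dataclass
class EpochSet:
    """Per-trial two-channel windows plus QC state.

    ``rel_time`` holds the common time grid (s, relative to instruction
    onset); all epochs share it.
    """

    rel_time: np.ndarray
    sampling_rate: float
    epochs: list
    normalized: bool = False
    baseline_corrected: bool = False
    n_dropped_out_of_recording: int = 0

    def copy(self) -> "EpochSet":
        return EpochSet(self.rel_time.copy(), self.sampling_rate,
                        [e.copy() for e in self.epochs],
                        self.normalized, self.baseline_corrected,
                        self.n_dropped_out_of_recording)

    @property
    def kept_epochs(self) -> list:
        return [e for e in self.epochs if e.kept]

    @property
    def n_kept(self) -> int:
        return sum(1 for e in self.epochs if e.kept)

    def qc_summary(self) -> dict:
        counts = {KEPT: 0, EXCLUDED_ARTIFACT: 0, EXCLUDED_RANGE: 0, EXCLUDED_MANUAL: 0}
        for e in self.epochs:
            counts[e.qc_status] = counts.get(e.qc_status, 0) + 1
        counts["dropped_out_of_recording"] = self.n_dropped_out_of_recording
        return counts


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def downsample(rec: BilateralRecording, target_rate: float) -> BilateralRecording:
    """Reduce the sampling rate by non-overlapping block averaging.

    The rate ratio must be an integer; each output sample is the mean of
    ``ratio`` consecutive input samples (implicit anti-aliasing).
    """
    ratio_f = rec.sampling_rate / target_rate
    ratio = int(round(ratio_f))
    if ratio < 1 or abs(ratio_f - ratio) > 1e-9:
        raise PreprocessError(
            f"sampling rate {rec.sampling_rate} Hz is not an integer multiple "
            f"of target rate {target_rate} Hz")
    if ratio == 1:
        return rec

    def block_mean(x: np.ndarray) -> np.ndarray:
        n = (len(x) // ratio) * ratio
        return x[:n].reshape(-1, ratio).mean(axis=1)

    return BilateralRecording(target_rate, block_mean(rec.left), block_mean(rec.right))


def epoch(rec: BilateralRecording, sched: TaskSchedule,
          cfg: PreprocessConfig) -> EpochSet:
    """Segment the recording into per-trial windows.

    One epoch is extracted per trial whose full window
    ``[onset + pre, onset + post)`` lies inside the recording; trials whose
    window exceeds the recording are dropped and counted.
    """
    if abs(rec.sampling_rate - cfg.target_rate) > 1e-9:
        raise PreprocessError(
            f"recording must be at target rate {cfg.target_rate} Hz "
            f"(got {rec.sampling_rate} Hz); run downsample first")
    fs = rec.sampling_rate
    pre, post = cfg.epoch_window
    n_win = int(round((post - pre) * fs))
    rel_time = pre + np.arange(n_win) / fs

    epochs: list[Epoch] = []
    dropped = 0
    for i, onset in enumerate(sched.trial_onsets):
        start = int(round((onset + pre) * fs))
        if start < 0 or start + n_win > rec.n_samples:
            dropped += 1
            continue
        epochs.append(Epoch(
            trial_index=i + 1,
            letter=sched.letters[i],
            left=rec.left[start:start + n_win].copy(),
            right=rec.right[start:start + n_win].copy(),
        ))
    if not epochs:
        raise InsufficientEpochsError("no trial window lies inside the recording")
    return EpochSet(rel_time, fs, epochs, n_dropped_out_of_recording=dropped)


def detect_artifacts(epochs: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Detect spikes and dropouts by session-level quantile bounds.

    Bounds are the (0.0001, 0.9999) quantiles computed per channel over all
    epoched samples of the session.  Within each epoch, a single outlying
    sample is replaced by that epoch-channel's mean (computed excluding the
    outlier); an epoch containing two or more outliers across both channels
    is excluded.
    """
    if epochs.normalized:
        raise PreprocessError("artifact detection must precede normalization")
    out = epochs.copy()
    kept = out.kept_epochs
    if not kept:
        return out
    bounds = {}
    for chan in ("left", "right"):
        allv = np.concatenate([getattr(e, chan) for e in kept])
        bounds[chan] = np.quantile(allv, cfg.quantile_bounds)
    for e in kept:
        masks = {}
        total = 0
        for chan in ("left", "right"):
            lo, hi = bounds[chan]
            x = getattr(e, chan)
            m = (x < lo) | (x > hi)
            masks[chan] = m
            total += int(m.sum())
        if total == 0:
            continue
        if total == 1:
            for chan, m in masks.items():
                if m.any():
                    x = getattr(e, chan)
                    x[m] = x[~m].mean()
        else:
            e.qc_status = EXCLUDED_ARTIFACT
    return out


def normalize(epochs: EpochSet) -> EpochSet:
    """Express each channel as a percentage of its session-level mean.

    The mean is taken per channel over all samples of the kept epochs, so
    the kept-epoch mean of each channel is exactly 100 afterwards.  This
    removes dependence on the insonation angle and vessel diameter.
    """
    if epochs.normalized:
        return epochs.copy()
    out = epochs.copy()
    kept = out.kept_epochs
    if not kept:
        raise InsufficientEpochsError("no kept epochs to normalize")
    for chan in ("left", "right"):
        mean = np.concatenate([getattr(e, chan) for e in kept]).mean()
        if mean <= 0:
            raise PreprocessError(
                f"non-physiological {chan} channel: session mean {mean:.3g} <= 0")
        for e in out.epochs:
            setattr(e, chan, getattr(e, chan) / mean * 100.0)
    out.normalized = True
    return out


def _integrate_cycles(x: np.ndarray, fs: float) -> tuple:
    """Replace cardiac cycles by their means, re-interpolated onto the grid.

    Cycles are delimited by successive diastolic troughs (local minima at
    least ``MIN_INTERBEAT_S`` apart).  Each cycle's time-mean is assigned to
    the cycle midpoint and values are linearly interpolated back onto the
    original sample grid (edge-held beyond the outermost midpoints).
    Returns ``(signal, warn)`` where ``warn`` is True when fewer than two
    troughs were found and the signal was passed through unchanged.
    """
    distance = max(1, int(np.ceil(MIN_INTERBEAT_S * fs)))
    troughs, _ = find_peaks(-x, distance=distance)
    if len(troughs) < 2:
        return x.copy(), True
    # refine trough positions to sub-sample precision (parabola through
    # the three samples around each minimum); cycle boundaries at integer
    # sample positions would otherwise bias the cycle means first-order in
    # the mismatch between sample spacing and cardiac period
    pos = troughs.astype(float)
    for j, k in enumerate(troughs):
        if 0 < k < len(x) - 1:
            denom = x[k - 1] - 2.0 * x[k] + x[k + 1]
            if denom > 0:
                delta = 0.5 * (x[k - 1] - x[k + 1]) / denom
                pos[j] = k + float(np.clip(delta, -0.5, 0.5))
    grid = np.arange(len(x), dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (x[1:] + x[:-1]))))
    cum_at = np.interp(pos, grid, cum)
    spans = np.diff(pos)
    means = np.diff(cum_at) / spans
    mids = 0.5 * (pos[:-1] + pos[1:])
    return np.interp(grid, mids, means), False


def heart_cycle_integrate(epochs: EpochSet) -> EpochSet:
    """Remove heart-beat confounds by per-cardiac-cycle integration."""
    if epochs.baseline_corrected:
        raise PreprocessError("heart-cycle integration must precede baseline correction")
    out = epochs.copy()
    for e in out.kept_epochs:
        left, warn_l = _integrate_cycles(e.left, out.sampling_rate)
        right, warn_r = _integrate_cycles(e.right, out.sampling_rate)
        e.left, e.right = left, right
        e.hci_warn = warn_l or warn_r
    return out


def baseline_correct(epochs: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Subtract the pre-instruction rest baseline from each epoch/channel.

    The mean over ``baseline_window`` (the 8 s of rest preceding the
    instruction screen at the defaults) is subtracted, yielding Delta-%
    units.  The pre-subtraction normalized values are retained on each
    epoch for the subsequent range-rejection test.
    """
    if not epochs.normalized:
        raise PreprocessError("baseline correction requires normalized epochs")
    out = epochs.copy()
    lo, hi = cfg.baseline_window
    mask = (out.rel_time >= lo) & (out.rel_time < hi)
    if not mask.any():
        raise PreprocessError("baseline window is empty on the epoch time grid")
    for e in out.epochs:
        e.left_norm = e.left.copy()
        e.right_norm = e.right.copy()
        e.left = e.left - e.left[mask].mean()
        e.right = e.right - e.right[mask].mean()
    out.baseline_corrected = True
    return out


def reject_out_of_range(epochs: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Exclude epochs whose normalized values leave the 60-140 % band.

    The test is applied to the pre-baseline-subtraction normalized values
    (the band is only meaningful on the mean-100 scale) with strict
    inequalities: exactly 60.0 or 140.0 is kept.
    """
    if not epochs.normalized:
        raise PreprocessError("range rejection requires normalized epochs")
    out = epochs.copy()
    lo, hi = cfg.range_bounds
    for e in out.kept_epochs:
        for chan in ("left", "right"):
            vals = getattr(e, f"{chan}_norm")
            if vals is None:
                vals = getattr(e, chan)
            if np.any(vals < lo) or np.any(vals > hi):
                e.qc_status = EXCLUDED_RANGE
                break
    return out


def manual_exclude(epochs: EpochSet, trial_indices: Sequence[int]) -> EpochSet:
    """Apply an externally supplied (visual-inspection) exclusion list."""
    out = epochs.copy()
    exclude = set(int(i) for i in trial_indices)
    for e in out.epochs:
        if e.trial_index in exclude and e.kept:
            e.qc_status = EXCLUDED_MANUAL
    return out


def preprocess_session(rec: BilateralRecording, sched: TaskSchedule,
                       cfg: PreprocessConfig | None = None,
                       manual_exclusions: Sequence[int] = ()) -> EpochSet:
    """Run the full preprocessing chain on a raw recording.

    Order: downsample, epoch, artifact detection, normalization,
    heart-cycle integration, baseline correction, range rejection, plus an
    optional manual exclusion list applied after artifact detection.
    """
    cfg = cfg or PreprocessConfig()
    rec = downsample(rec, cfg.target_rate)
    es = epoch(rec, sched, cfg)
    es = detect_artifacts(es, cfg)
    if manual_exclusions:
        es = manual_exclude(es, manual_exclusions)
    es = normalize(es)
    es = heart_cycle_integrate(es)
    es = baseline_correct(es, cfg)
    es = reject_out_of_range(es, cfg)
    return es
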