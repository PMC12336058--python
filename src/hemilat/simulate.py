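"""Synthetic bilateral CBFV sessions, retest cohorts, VHT trials and ROI maps.

The generator treats a measured laterality index as the sum of three
components: a stable person-specific *trait* asymmetry, a session-specific
*state* offset, and *measurement noise*.  A simulated channel is

    v(t) = base * (1 + pulsatility(t)) * (1 + response(t)/100 + noise(t)),

with a cardiac pulsatility waveform at ``hr_bpm`` (a peaked single-trough
pulse, so per-cycle integration is well defined), a task-locked response
that ramps up after word-generation onset and plateaus through the period
of interest, and AR(1) measurement noise.  Laterality enters as an
antisymmetric split of a common response amplitude:

    left amplitude  = response_amplitude - (trait + state)/2
    right amplitude = response_amplitude + (trait + state)/2

so that the pipeline's expected LI (right - left convention) equals
``trait + state`` up to the small attenuation introduced by session-mean
normalization, making parameter-recovery tests sharp.  Every
generator is bit-reproducible under its seed, and a truth ledger records
the generating parameters and injected artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .fmri import StatMapROI
from .preprocess import BilateralRecording, TaskSchedule, DEFAULT_LETTERS
from .vht import LVF, RVF, VHTTrial

__all__ = [
    "SessionSimConfig", "SimTruth", "RetestCohortConfig", "SubjectRecord",
    "default_schedule", "generate_session", "generate_retest_cohort",
    "generate_vht_trials", "generate_stat_maps",
]


def default_schedule(n_trials: int = 16, first_onset: float = 15.0,
                     instruction_dur: float = 3.0, task_dur: float = 20.0,
                     rest_dur: float = 15.0) -> TaskSchedule:
    """The standard 16-trial verbal-fluency schedule: 3 s instruction,
    20 s word generation, 15 s rest (38 s trial period)."""
    period = instruction_dur + task_dur + rest_dur
    onsets = tuple(first_onset + i * period for i in range(n_trials))
    letters = tuple(DEFAULT_LETTERS[i % len(DEFAULT_LETTERS)]
                    for i in range(n_trials))
    return TaskSchedule(onsets, instruction_dur, task_dur, rest_dur, letters)


@dataclass(frozen=True)
class SessionSimConfig:
    """Parameters of one simulated fTCD session.

    Amplitudes (``trait_li``, ``state_offset``, ``response_amplitude``,
    ``noise_sd``) are in percent of the channel mean, i.e. the units the
    pipeline produces after normalization.  ``spike_rate`` and
    ``dropout_rate`` are events per minute; each event corrupts an 80 ms
    stretch of one channel (spikes multiply by 2.5, dropouts by 0.15).
    """

    trait_li: float = 0.0
    state_offset: float = 0.0
    sampling_rate: float = 100.0
    base_velocity: float = 60.0      # cm/s, mean MCA flow velocity
    hr_bpm: float = 70.0
    pulsatility_frac: float = 0.25   # peak-to-mean fraction of the cardiac pulse
    response_amplitude: float = 4.0  # % bilateral task-evoked rise
    response_onset_lag_s: float = 3.0
    response_fall_s: float = 5.0
    noise_sd: float = 1.0            # % stationary SD of the AR(1) noise
    noise_ar: float = 0.9
    spike_rate: float = 0.0
    dropout_rate: float = 0.0
    schedule: Optional[TaskSchedule] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pulsatility_frac < 1.0:
            raise ValueError("pulsatility_frac must be in [0, 1)")
        for name in ("spike_rate", "dropout_rate", "noise_sd", "hr_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValueError("noise_ar must be in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters of a session, for parameter-recovery tests."""

    trait_li: float
    state_offset: float
    expected_li: float
    artifacts: tuple  # (time_s, kind, channel) triples
    seed: int


ARTIFACT_DUR_S = 0.08
SPIKE_GAIN = 2.5
DROPOUT_GAIN = 0.15


def _cardiac_wave(t: np.ndarray, hr_bpm: float, frac: float,
                  phase: float) -> np.ndarray:
    """Zero-mean pulsatile waveform with a single trough per cycle.

    Shape ((1+cos)/2)^2 has cycle mean 3/8; scaling by frac/(1-3/8) makes
    the systolic peak exceed the mean by ``frac`` of the mean.
    """
    if frac == 0.0 or hr_bpm == 0.0:
        return np.zeros_like(t)
    theta = 2.0 * math.pi * (hr_bpm / 60.0) * t + phase
    s = ((1.0 + np.cos(theta)) / 2.0) ** 2
    return (s - 0.375) * (frac / 0.625)


def _response_shape(t: np.ndarray, sched: TaskSchedule, lag: float,
                    fall: float) -> np.ndarray:
    """Task-response time course in [0, 1]: per trial, a linear ramp of
    ``lag`` seconds starting at word-generation onset, a plateau until the
    end of the task, and a linear fall of ``fall`` seconds."""
    f = np.zeros_like(t)
    for onset in sched.trial_onsets:
        task_on = onset + sched.instruction_dur
        task_off = task_on + sched.task_dur
        seg = np.zeros_like(t)
        if lag > 0:
            seg = np.clip((t - task_on) / lag, 0.0, 1.0)
        else:
            seg = (t >= task_on).astype(float)
        if fall > 0:
            seg = seg * np.clip(1.0 - (t - task_off) / fall, 0.0, 1.0)
        else:
            seg = seg * (t < task_off)
        np.maximum(f, seg, out=f)
    return f


def _ar1(rng: np.random.Generator, n: int, sd: float, ar: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - ar * ar)
    eps = rng.normal(0.0, innov_sd, n)
    x_prev = rng.normal(0.0, sd)  # stationary start
    x, _ = lfilter([1.0], [1.0, -ar], eps, zi=np.array([ar * x_prev]))
    return x


def _inject_artifacts(rng: np.random.Generator, channels: dict, fs: float,
                      duration: float, rate: float, gain: float,
                      kind: str) -> list:
    events = []
    n_events = rng.poisson(rate * duration / 60.0)
    n_run = max(1, int(round(ARTIFACT_DUR_S * fs)))
    n_samples = len(next(iter(channels.values())))
    for _ in range(n_events):
        chan = "left" if rng.random() < 0.5 else "right"
        start = int(rng.integers(0, max(1, n_samples - n_run)))
        channels[chan][start:start + n_run] *= gain
        events.append((start / fs, kind, chan))
    return events


def generate_session(cfg: SessionSimConfig) -> tuple:
    """Simulate one session.

    Returns ``(recording, schedule, truth)`` where the recording is at
    ``cfg.sampling_rate`` and the schedule is the standard 16-trial
    design unless overridden in the config.
    """
    sched = cfg.schedule or default_schedule()
    fs = cfg.sampling_rate
    duration = sched.trial_onsets[-1] + sched.instruction_dur + sched.task_dur + 7.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(cfg.seed)

    phase = rng.uniform(0.0, 2.0 * math.pi)
    pulse = _cardiac_wave(t, cfg.hr_bpm, cfg.pulsatility_frac, phase)
    f = _response_shape(t, sched, cfg.response_onset_lag_s, cfg.response_fall_s)
    d = cfg.trait_li + cfg.state_offset
    amp_left = cfg.response_amplitude - d / 2.0
    amp_right = cfg.response_amplitude + d / 2.0
    noise_l = _ar1(rng, n, cfg.noise_sd / 100.0, cfg.noise_ar)
    noise_r = _ar1(rng, n, cfg.noise_sd / 100.0, cfg.noise_ar)

    base = cfg.base_velocity
    channels = {
        "left": base * (1.0 + pulse) * (1.0 + amp_left / 100.0 * f + noise_l),
        "right": base * (1.0 + pulse) * (1.0 + amp_right / 100.0 * f + noise_r),
    }
    events = []
    events += _inject_artifacts(rng, channels, fs, duration, cfg.spike_rate,
                                SPIKE_GAIN, "spike")
    events += _inject_artifacts(rng, channels, fs, duration, cfg.dropout_rate,
                                DROPOUT_GAIN, "dropout")
    rec = BilateralRecording(fs, channels["left"], channels["right"])
    truth = SimTruth(cfg.trait_li, cfg.state_offset, d, tuple(events), cfg.seed)
    return rec, sched, truth


@dataclass(frozen=True)
class RetestCohortConfig:
    """Cohort of subjects measured in two (or more) sessions.

    ``trait_modes`` is a mixture of Gaussians (mean, sd, weight) for the
    population trait-LI distribution.  The default — a dominant
    left-lateralized mode around -3 Delta-% plus a near-zero minority —
    is a synthetic convention qualitatively mimicking empirical verbal
    fluency LI distributions.  ``state_sd`` is the SD of the independent
    per-session state offsets; it has no empirical anchor and defaults to
    0.8 Delta-%.
    """

    n_subjects: int = 68
    trait_modes: tuple = ((-3.0, 1.0, 0.85), (0.0, 0.5, 0.15))
    state_sd: float = 0.8
    sessions: int = 2
    session_template: SessionSimConfig = field(default_factory=SessionSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(m[2] for m in self.trait_modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"trait mixture weights must sum to 1 (got {w})")
        if self.state_sd < 0 or self.n_subjects < 1 or self.sessions < 1:
            raise ValueError("invalid cohort configuration")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    trait_li: float
    sessions: tuple  # of (BilateralRecording, TaskSchedule, SimTruth)


def generate_retest_cohort(cfg: RetestCohortConfig) -> list:
    """Generate a cohort: one trait draw per subject, an independent
    Normal(0, state_sd) state offset per session, sessions via
    :func:`generate_session`."""
    root = np.random.SeedSequence(cfg.seed)
    subject_seqs = root.spawn(cfg.n_subjects)
    means = np.array([m[0] for m in cfg.trait_modes])
    sds = np.array([m[1] for m in cfg.trait_modes])
    weights = np.array([m[2] for m in cfg.trait_modes])
    cohort = []
    for i, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        mode = rng.choice(len(weights), p=weights)
        trait = float(rng.normal(means[mode], sds[mode]))
        sessions = []
        for s in range(cfg.sessions):
            state = float(rng.normal(0.0, cfg.state_sd)) if cfg.state_sd > 0 else 0.0
            seed = int(rng.integers(0, 2 ** 31 - 1))
            scfg = replace(cfg.session_template, trait_li=trait,
                           state_offset=state, seed=seed)
            sessions.append(generate_session(scfg))
        cohort.append(SubjectRecord(f"sub-{i + 1:03d}", trait, tuple(sessions)))
    return cohort


def generate_vht_trials(n_per_field: int, p_lvf: float, p_rvf: float,
                        seed: int = 0, n_control: int = 0,
                        p_control: float = 0.98) -> list:
    """Bernoulli-correct VHT trials with counterbalanced fields.

    Each of ``n_per_field`` target words appears once in each hemifield;
    optional central-digit control trials are interleaved.
    """
    for name, p in (("p_lvf", p_lvf), ("p_rvf", p_rvf)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_per_field):
        word = f"word{i:03d}"
        trials.append(VHTTrial(word, LVF, bool(rng.random() < p_lvf)))
        trials.append(VHTTrial(word, RVF, bool(rng.random() < p_rvf)))
    for j in range(n_control):
        trials.append(VHTTrial(str(j % 10), None,
                               bool(rng.random() < p_control), is_control=True))
    order = rng.permutation(len(trials))
    return [trials[k] for k in order]


def generate_stat_maps(n_voxels_per_side: int, mean_left: float,
                       mean_right: float, noise_sd: float = 1.0,
                       seed: int = 0) -> tuple:
    """Gaussian ROI statistic values truncated at zero.

    Returns ``(roi, asymptotic_li)`` where the asymptotic LI is the
    sum-ratio limit (mean_right - mean_left)/(mean_right + mean_left) for
    positive means (NaN when the means sum to zero).
    """
    rng = np.random.default_rng(seed)
    left = np.maximum(0.0, rng.normal(mean_left, noise_sd, n_voxels_per_side))
    right = np.maximum(0.0, rng.normal(mean_right, noise_sd, n_voxels_per_side))
    total = mean_left + mean_right
    truth = (mean_right - mean_left) / total if total > 0 else float("nan")
    return StatMapROI(left, right), float(truth)
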