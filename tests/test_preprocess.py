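"""Unit and property tests for the CBFV preprocessing chain."""

import numpy as np
import pytest

from hemilat.preprocess import (
    KEPT, EXCLUDED_ARTIFACT, EXCLUDED_RANGE,
    BilateralRecording, InsufficientEpochsError, PreprocessConfig,
    PreprocessError, TaskSchedule, baseline_correct, detect_artifacts,
    downsample, epoch, heart_cycle_integrate, manual_exclude, normalize,
    preprocess_session, reject_out_of_range,
)
from hemilat.simulate import SessionSimConfig, default_schedule, generate_session

from conftest import raw_epochset


def make_rec(left, right=None, fs=100.0):
    left = np.asarray(left, float)
    right = left.copy() if right is None else np.asarray(right, float)
    return BilateralRecording(fs, left, right)


class TestDownsample:
    def test_constant_is_fixed_point(self):
        rec = make_rec(np.full(400, 80.0), fs=100.0)
        out = downsample(rec, 25.0)
        assert out.sampling_rate == 25.0
        assert out.n_samples == 100
        assert np.allclose(out.left, 80.0)
        assert np.allclose(out.right, 80.0)

    def test_block_means_of_four(self):
        rec = make_rec([1, 2, 3, 4, 5, 6, 7, 8], fs=100.0)
        out = downsample(rec, 25.0)
        assert np.allclose(out.left, [2.5, 6.5])

    def test_rate_ratio_four(self):
        rec = make_rec(np.arange(1000.0), fs=100.0)
        out = downsample(rec, 25.0)
        assert out.n_samples == rec.n_samples // 4

    def test_non_integer_ratio_rejected(self):
        rec = make_rec(np.arange(100.0), fs=100.0)
        with pytest.raises(PreprocessError, match="integer multiple"):
            downsample(rec, 40.0)


class TestHeartCycleIntegrate:
    def test_constant_passes_through(self):
        es = raw_epochset([np.full(950, 100.0)], [np.full(950, 100.0)])
        out = heart_cycle_integrate(es)
        assert np.allclose(out.epochs[0].left, 100.0)
        assert out.epochs[0].hci_warn  # no troughs found in a constant

    def test_sinusoid_flattens_to_offset(self):
        fs = 25.0
        t = np.arange(950) / fs
        v = 100.0 + 20.0 * np.sin(2 * np.pi * 1.2 * t)
        es = raw_epochset([v], [v], fs=fs)
        out = heart_cycle_integrate(es)
        assert not out.epochs[0].hci_warn
        assert np.max(np.abs(out.epochs[0].left - 100.0)) < 0.5

    def test_trend_preserved_against_cycle_mean_oracle(self):
        fs = 25.0
        t = np.arange(950) / fs
        v = 100.0 + t + 20.0 * np.sin(2 * np.pi * 1.2 * t)
        es = raw_epochset([v], [v], fs=fs)
        out = heart_cycle_integrate(es)
        # analytic oracle: the per-cycle mean of offset + trend + sinusoid
        # is the offset plus the trend evaluated at the cycle midpoint
        from scipy.signal import find_peaks
        troughs, _ = find_peaks(-v, distance=int(np.ceil(0.33 * fs)))
        assert len(troughs) >= 20
        for i in range(len(troughs) - 1):
            mid = int(round(0.5 * (troughs[i] + troughs[i + 1])))
            expected = 100.0 + t[mid]
            assert abs(out.epochs[0].left[mid] - expected) < 0.5


class TestEpoch:
    def test_sixteen_trials_default_window(self, cfg):
        sched = default_schedule()
        dur = sched.trial_onsets[-1] + 30.0
        n = int(dur * 25)
        rec = make_rec(np.full(n, 60.0), fs=25.0)
        es = epoch(rec, sched, cfg)
        assert len(es.epochs) == 16
        assert all(len(e.left) == 950 for e in es.epochs)
        assert len(es.rel_time) == 950

    def test_window_before_recording_start_dropped(self, cfg):
        onsets = tuple([5.0] + [60.0 + 38.0 * i for i in range(15)])
        sched = TaskSchedule(onsets, letters=["L"] * 16)
        n = int((onsets[-1] + 30.0) * 25)
        rec = make_rec(np.zeros(n) + 60.0, fs=25.0)
        es = epoch(rec, sched, cfg)
        assert len(es.epochs) == 15
        assert es.n_dropped_out_of_recording == 1
        assert es.epochs[0].trial_index == 2

    def test_recording_ending_exactly_at_last_window(self, cfg):
        onsets = tuple(10.0 + 38.0 * i for i in range(4))
        sched = TaskSchedule(onsets, letters=list("ABCD"))
        n = int(round((onsets[-1] + 28.0) * 25))  # ends exactly at onset+28
        rec = make_rec(np.full(n, 60.0), fs=25.0)
        es = epoch(rec, sched, cfg)
        assert len(es.epochs) == 4

    def test_empty_schedule_rejected(self):
        with pytest.raises(PreprocessError, match="no trials"):
            TaskSchedule((), letters=())

    def test_zero_extractable_epochs(self, cfg):
        sched = TaskSchedule((5.0,), letters=("A",))
        rec = make_rec(np.full(100, 60.0), fs=25.0)
        with pytest.raises(InsufficientEpochsError):
            epoch(rec, sched, cfg)

    def test_wrong_rate_rejected(self, cfg):
        sched = default_schedule()
        rec = make_rec(np.full(70000, 60.0), fs=100.0)
        with pytest.raises(PreprocessError, match="target rate"):
            epoch(rec, sched, cfg)


class TestDetectArtifacts:
    def setup_epochs(self, spikes=()):
        # 16 epochs of 950 samples (session scale); values are clipped to
        # [59.5, 60.5] so the extreme order statistics are tied and the
        # strict quantile bounds flag nothing but the injected spikes
        rng = np.random.default_rng(7)
        base = [np.clip(60.0 + rng.uniform(-1.2, 1.2, 950), 59.5, 60.5)
                for _ in range(16)]
        left = [b.copy() for b in base]
        right = [b.copy() for b in base]
        for (epoch_i, sample_i, value) in spikes:
            left[epoch_i][sample_i] = value
        return raw_epochset(left, right)

    def test_no_outliers_all_kept(self, cfg):
        es = self.setup_epochs()
        out = detect_artifacts(es, cfg)
        assert all(e.qc_status == KEPT for e in out.epochs)

    def test_single_spike_replaced_by_epoch_mean(self, cfg):
        es = self.setup_epochs(spikes=[(2, 100, 600.0)])
        before = es.epochs[2].left.copy()
        out = detect_artifacts(es, cfg)
        assert out.epochs[2].qc_status == KEPT
        mask = np.ones(950, bool)
        mask[100] = False
        assert out.epochs[2].left[100] == pytest.approx(before[mask].mean())
        assert np.array_equal(out.epochs[2].left[mask], before[mask])

    def test_two_spikes_exclude_epoch(self, cfg):
        es = self.setup_epochs(spikes=[(2, 100, 600.0), (2, 500, 700.0)])
        out = detect_artifacts(es, cfg)
        assert out.epochs[2].qc_status == EXCLUDED_ARTIFACT
        assert all(e.qc_status == KEPT for i, e in enumerate(out.epochs) if i != 2)


class TestNormalize:
    def test_mean_100_is_fixed_point(self):
        es = raw_epochset([[50.0, 100.0, 150.0]], [[50.0, 100.0, 150.0]])
        out = normalize(es)
        assert np.allclose(out.epochs[0].left, [50, 100, 150])

    def test_hand_arithmetic(self):
        es = raw_epochset([[1.0, 2.0, 3.0]], [[2.0, 2.0, 2.0]])
        out = normalize(es)
        assert np.allclose(out.epochs[0].left, [50, 100, 150])
        assert np.allclose(out.epochs[0].right, [100, 100, 100])

    def test_postcondition_mean_exactly_100(self):
        rng = np.random.default_rng(1)
        es = raw_epochset([rng.uniform(40, 80, 950) for _ in range(4)],
                          [rng.uniform(40, 80, 950) for _ in range(4)])
        out = normalize(es)
        for chan in ("left", "right"):
            allv = np.concatenate([getattr(e, chan) for e in out.kept_epochs])
            assert allv.mean() == pytest.approx(100.0, abs=1e-9)

    def test_excluded_epochs_ignored_in_mean(self):
        es = raw_epochset([[1.0, 1.0], [9.0, 9.0]], [[1.0, 1.0], [1.0, 1.0]])
        es.epochs[1].qc_status = EXCLUDED_ARTIFACT
        out = normalize(es)
        assert np.allclose(out.epochs[0].left, 100.0)

    def test_nonpositive_mean_rejected(self):
        es = raw_epochset([[-1.0, 1.0]], [[1.0, 1.0]])
        with pytest.raises(PreprocessError, match="non-physiological"):
            normalize(es)


class TestBaselineCorrect:
    def small_cfg(self):
        return PreprocessConfig(epoch_window=(-2.0, 2.0),
                                baseline_window=(-2.0, 0.0),
                                poi_window=(0.0, 2.0))

    def test_epoch_equal_to_baseline_becomes_zero(self):
        es = raw_epochset([np.full(100, 98.0)], [np.full(100, 98.0)],
                          fs=25.0, window=(-2.0, 2.0))
        es.normalized = True
        out = baseline_correct(es, self.small_cfg())
        assert np.allclose(out.epochs[0].left, 0.0)

    def test_poi_shift_arithmetic(self):
        fs, cfg = 25.0, self.small_cfg()
        v = np.where(np.arange(100) < 50, 98.0, 103.0)  # baseline 98, POI 103
        es = raw_epochset([v], [v], fs=fs, window=(-2.0, 2.0))
        es.normalized = True
        out = baseline_correct(es, cfg)
        assert np.allclose(out.epochs[0].left[50:], 5.0)

    def test_baseline_window_mean_zero_after_correction(self):
        rng = np.random.default_rng(3)
        cfg = self.small_cfg()
        es = raw_epochset([rng.uniform(90, 110, 100)],
                          [rng.uniform(90, 110, 100)],
                          fs=25.0, window=(-2.0, 2.0))
        es.normalized = True
        out = baseline_correct(es, cfg)
        mask = (out.rel_time >= -2.0) & (out.rel_time < 0.0)
        for chan in ("left", "right"):
            assert getattr(out.epochs[0], chan)[mask].mean() == pytest.approx(
                0.0, abs=1e-9)

    def test_requires_normalized(self):
        es = raw_epochset([np.full(100, 98.0)], [np.full(100, 98.0)],
                          fs=25.0, window=(-2.0, 2.0))
        with pytest.raises(PreprocessError, match="normalized"):
            baseline_correct(es, self.small_cfg())


class TestRejectOutOfRange:
    def build(self, values):
        es = raw_epochset([np.asarray(v, float) for v in values],
                          [np.full(len(values[0]), 100.0)] * len(values),
                          fs=1.0, window=(-2.0, len(values[0]) - 2.0))
        es.normalized = True
        return es

    def test_in_band_kept(self, cfg):
        es = self.build([[60.0, 100.0, 140.0]])
        out = reject_out_of_range(es, cfg)
        assert out.epochs[0].qc_status == KEPT

    def test_strict_boundary(self, cfg):
        es = self.build([[59.9, 100.0], [60.0, 100.0], [100.0, 140.1]])
        out = reject_out_of_range(es, cfg)
        assert out.epochs[0].qc_status == EXCLUDED_RANGE
        assert out.epochs[1].qc_status == KEPT
        assert out.epochs[2].qc_status == EXCLUDED_RANGE

    def test_uses_pre_baseline_values(self, cfg):
        # after baseline correction the values are near 0; the 60-140 test
        # must run on the retained pre-subtraction snapshot
        small = PreprocessConfig(epoch_window=(-2.0, 2.0),
                                 baseline_window=(-2.0, 0.0),
                                 poi_window=(0.0, 2.0))
        es = raw_epochset([np.full(100, 100.0)], [np.full(100, 100.0)],
                          fs=25.0, window=(-2.0, 2.0))
        es.normalized = True
        out = reject_out_of_range(baseline_correct(es, small), cfg)
        assert out.epochs[0].qc_status == KEPT


class TestPipelineProperties:
    def test_channel_swap_symmetry_full_chain(self, cfg):
        scfg = SessionSimConfig(trait_li=-2.5, noise_sd=0.8, seed=11)
        rec, sched, _ = generate_session(scfg)
        es = preprocess_session(rec, sched, cfg)
        es_sw = preprocess_session(rec.swapped(), sched, cfg)
        assert [e.qc_status for e in es.epochs] == [e.qc_status for e in es_sw.epochs]
        for a, b in zip(es.epochs, es_sw.epochs):
            assert np.array_equal(a.left, b.right)
            assert np.array_equal(a.right, b.left)

    def test_kept_count_monotone_through_qc(self, cfg):
        scfg = SessionSimConfig(trait_li=-2.0, spike_rate=1.0, seed=5)
        rec, sched, _ = generate_session(scfg)
        rec = downsample(rec, cfg.target_rate)
        es = epoch(rec, sched, cfg)
        counts = [es.n_kept]
        es = detect_artifacts(es, cfg)
        counts.append(es.n_kept)
        es = normalize(es)
        es = heart_cycle_integrate(es)
        es = baseline_correct(es, cfg)
        counts.append(es.n_kept)
        es = reject_out_of_range(es, cfg)
        counts.append(es.n_kept)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_heart_cycle_integration_preserves_slow_dynamics(self, cfg):
        # artifact-free pulsatile session: POI means with and without the
        # integration stage differ by less than the cardiac ripple bound
        from hemilat.laterality import compute_li
        scfg = SessionSimConfig(trait_li=-3.0, noise_sd=0.0, seed=2)
        rec, sched, _ = generate_session(scfg)
        rec = downsample(rec, cfg.target_rate)
        es0 = epoch(rec, sched, cfg)
        es0 = detect_artifacts(es0, cfg)
        es0 = normalize(es0)
        with_hci = reject_out_of_range(
            baseline_correct(heart_cycle_integrate(es0), cfg), cfg)
        without_hci = reject_out_of_range(baseline_correct(es0, cfg), cfg)
        li_with = compute_li(with_hci, cfg).li
        li_without = compute_li(without_hci, cfg).li
        ripple_bound = 100.0 * scfg.pulsatility_frac
        assert abs(li_with - li_without) < ripple_bound
        assert abs(li_with - li_without) < 0.5  # POI-mean scale in practice

    def test_normalize_idempotent(self):
        rng = np.random.default_rng(4)
        es = raw_epochset([rng.uniform(50, 70, 950)], [rng.uniform(50, 70, 950)])
        once = normalize(es)
        twice = normalize(once)
        assert np.allclose(once.epochs[0].left, twice.epochs[0].left)

    def test_manual_exclusion(self, cfg):
        es = raw_epochset([np.full(10, 60.0)] * 3, [np.full(10, 60.0)] * 3)
        out = manual_exclude(es, [2])
        assert [e.qc_status for e in out.epochs] == [
            KEPT, "excluded_manual", KEPT]
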