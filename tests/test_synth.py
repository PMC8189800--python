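"""Synthetic generator: target sequences, recordings, offset samples."""

import numpy as np
import pytest
from scipy import stats

from fixoffset import (SyntheticScenario, MixtureSpec, estimate_latency,
                       generate_offset_sample, generate_recording,
                       generate_target_sequence, offset_series)
from fixoffset.synth import (EVENT_BLINK, EVENT_FIXATION, EVENT_SACCADE,
                             EVENT_AS_PLATEAU, EVENT_AS_SACCADE)


class TestTargetSequence:
    def test_invariants_at_task_defaults(self):
        seq = generate_target_sequence(100, ranges=(15, 9), min_step=2, seed=1)
        pos = seq.positions
        assert pos.shape == (100, 2)
        assert (np.abs(pos[:, 0]) <= 15).all()
        assert (np.abs(pos[:, 1]) <= 9).all()
        steps = np.hypot(*np.diff(pos, axis=0).T)
        assert (steps >= 2.0).all()

    def test_same_seed_identical(self):
        a = generate_target_sequence(50, seed=7).positions
        b = generate_target_sequence(50, seed=7).positions
        np.testing.assert_array_equal(a, b)

    def test_uniform_coverage_chi_square(self):
        # 10 equal bins on x over n=10000 positions; alpha = 0.01
        seq = generate_target_sequence(10000, seed=1)
        counts, _ = np.histogram(seq.positions[:, 0], bins=10, range=(-15, 15))
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=9)

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError):
            generate_target_sequence(10, ranges=(1, 1), min_step=10)

    def test_zero_targets_raises(self):
        with pytest.raises(ValueError):
            generate_target_sequence(0)


def _quiet_scenario(**kw):
    base = dict(seed=0, fixation_noise_sd=0.0, blink_rate=0.0,
                anticipatory_hazard_slope=0.0,
                offset_components=MixtureSpec((0.0,), (0.0,), (1.0,)),
                latency_sd_ms=0.0, latency_mean_ms=237.0)
    base.update(kw)
    return SyntheticScenario(**base)


class TestGenerateRecording:
    def test_no_perturbations_gaze_equals_fixated_target(self):
        seq = generate_target_sequence(8, seed=2)
        rec, gt = generate_recording(seq, _quiet_scenario())
        m = gt.fix_trial >= 0
        err = np.hypot(rec.gaze_x[m] - seq.positions[gt.fix_trial[m], 0],
                       rec.gaze_y[m] - seq.positions[gt.fix_trial[m], 1])
        assert err.max() == 0.0

    def test_fixed_seed_bitwise_identical(self):
        seq = generate_target_sequence(5, seed=3)
        sc = SyntheticScenario(seed=3, blink_rate=0.2,
                               anticipatory_hazard_slope=0.01)
        r1, g1 = generate_recording(seq, sc)
        r2, g2 = generate_recording(seq, sc)
        np.testing.assert_array_equal(r1.gaze_x, r2.gaze_x)
        np.testing.assert_array_equal(r1.gaze_y, r2.gaze_y)
        assert g1.saccade_spans == g2.saccade_spans
        assert g1.blink_spans == g2.blink_spans

    def test_ground_truth_annotations_match_inserted_events(self):
        seq = generate_target_sequence(10, seed=4)
        sc = SyntheticScenario(seed=4, blink_rate=0.3,
                               anticipatory_hazard_slope=0.05)
        rec, gt = generate_recording(seq, sc)
        ev = gt.events
        for a, b in gt.saccade_spans:
            assert (ev[a:b] != EVENT_FIXATION).all()
        for a, b in gt.blink_nan_spans:
            assert np.isnan(rec.gaze_x[a:b]).all()
            assert (ev[a:b] == EVENT_BLINK).all()
        assert len(gt.as_spans) == len(gt.as_plateau_spans) == len(gt.as_trials)
        for a, b in gt.as_spans:
            assert (ev[a:b] == EVENT_AS_SACCADE).all() or (
                ev[a:b] == EVENT_BLINK).any()
        assert len(gt.saccade_spans) == seq.n_targets - 1

    def test_saccade_peak_velocity_exceeds_detection_threshold(self):
        seq = generate_target_sequence(10, seed=5)
        rec, gt = generate_recording(seq, _quiet_scenario(seed=5))
        v = np.hypot(np.gradient(rec.gaze_x), np.gradient(rec.gaze_y)) * rec.fs
        for a, b in gt.saccade_spans:
            assert np.nanmax(v[a:b]) > 55.0

    def test_instant_saccades_give_exact_latency_recovery(self):
        # downstream pipeline oracle: planted shift of 237 samples
        seq = generate_target_sequence(6, seed=6)
        sc = _quiet_scenario(seed=6, saccade_base_ms=0.0, saccade_ms_per_deg=0.0)
        rec, _ = generate_recording(seq, sc)
        assert estimate_latency(rec) == 237

    def test_anticipatory_hazard_increases_with_trial(self):
        sc = SyntheticScenario(seed=9, blink_rate=0.0,
                               anticipatory_hazard_slope=0.004)
        counts = np.zeros(40)
        for r in range(25):
            seq = generate_target_sequence(40, seed=300 + r)
            _, gt = generate_recording(seq, sc, subject=f"S{r:03d}")
            for t in gt.as_trials:
                counts[t] += 1
        assert np.corrcoef(np.arange(40), counts)[0, 1] > 0

    def test_planted_offset_visible_in_offset_series(self):
        spec = MixtureSpec((1.0,), (0.0,), (1.0,))
        seq = generate_target_sequence(6, seed=10)
        rec, gt = generate_recording(seq, _quiet_scenario(offset_components=spec))
        off = offset_series(rec)
        m = gt.fix_trial >= 0
        # offset magnitude is planted relative to the *fixated* target;
        # measure only where the fixated target is the current target
        trial_idx = np.arange(rec.n_samples) // 1000
        m &= gt.fix_trial == trial_idx
        # the planted offset is Euclidean in the tangent plane; the angular
        # reading compresses it by up to ~3% at eccentric targets
        np.testing.assert_allclose(off[m], 1.0, atol=0.05)
        assert abs(np.median(off[m]) - 1.0) < 0.04


class TestOffsetSample:
    def test_single_component_mean_within_3se(self):
        x = generate_offset_sample((1.0,), (0.1,), (1.0,), 500, seed=1)
        assert abs(x.mean() - 1.0) < 3 * 0.1 / np.sqrt(500)

    def test_bimodal_sample_separates_cleanly(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score
        x = generate_offset_sample((0.5, 2.0), (0.05, 0.05), (0.5, 0.5),
                                   400, seed=2)
        labels = KMeans(2, n_init=5, random_state=0).fit_predict(x[:, None])
        assert silhouette_score(x[:, None], labels) > 0.8

    def test_truncation_keeps_offsets_nonnegative(self):
        x = generate_offset_sample((0.05,), (0.2,), (1.0,), 2000, seed=3)
        assert (x >= 0).all()

    def test_n_zero_raises(self):
        with pytest.raises(ValueError):
            generate_offset_sample((1.0,), (0.1,), (1.0,), 0)

    def test_invalid_weights_raise(self):
        with pytest.raises(ValueError):
            generate_offset_sample((1.0, 2.0), (0.1, 0.1), (0.7, 0.7), 10)
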