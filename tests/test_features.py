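"""The 67-feature epoch registry and its five families."""

import numpy as np
import pytest

from sonostage.audio_io import FRAME_SAMPLES, FRAMES_PER_EPOCH, EpochAudio
from sonostage.detection import DB_FLOOR, FrameLabel, frame_features_matrix
from sonostage.enhancement import NoiseProfile, N_BINS
from sonostage.features import (
    BACKGROUND_NOISE_NAMES,
    BETWEEN_BREATHING_NAMES,
    BODY_MOVEMENT_NAMES,
    FAMILY_SIZES,
    FEATURE_INDEX,
    FEATURE_NAMES,
    N_FEATURES,
    PERSONALIZATION_NAMES,
    WITHIN_BREATHING_NAMES,
    SubjectMeta,
    background_noise_features,
    between_breathing_features,
    body_movement_features,
    extract_epoch_features,
    personalization_features,
    segment_breath_events,
    within_breathing_features,
)
from tests.conftest import make_stage_epoch


def curves_of(frame_classes, prob=0.9):
    """Hand-built probability curves: one dominant class per frame."""
    curves = np.full((FRAMES_PER_EPOCH, 4), (1 - prob) / 3)
    for i, c in enumerate(frame_classes):
        curves[i, c] = prob
    return curves


def flat_profile(level_db=-60.0):
    ms = 10 ** (level_db / 10)
    return NoiseProfile(np.full(N_BINS, ms * FRAME_SAMPLES), ms, 1)


OTHER_ONLY = [int(FrameLabel.OTHER)] * FRAMES_PER_EPOCH


class TestRegistry:
    def test_sizes_and_bijection(self):
        assert len(FEATURE_NAMES) == N_FEATURES == 67
        assert (len(WITHIN_BREATHING_NAMES), len(BETWEEN_BREATHING_NAMES),
                len(BODY_MOVEMENT_NAMES), len(BACKGROUND_NOISE_NAMES),
                len(PERSONALIZATION_NAMES)) == (33, 12, 10, 8, 4)
        assert tuple(FAMILY_SIZES.values()) == (33, 12, 10, 8, 4)
        assert len(set(FEATURE_NAMES)) == 67
        assert all(FEATURE_NAMES[i] == n for n, i in FEATURE_INDEX.items())


class TestSegmentation:
    def test_pure_other_gives_no_events(self):
        assert segment_breath_events(curves_of(OTHER_ONLY)) == []

    def test_two_inhale_runs(self):
        classes = list(OTHER_ONLY)
        classes[100:110] = [int(FrameLabel.INHALE)] * 10
        classes[300:310] = [int(FrameLabel.INHALE)] * 10
        events = segment_breath_events(curves_of(classes))
        assert len(events) == 2
        assert all(e.kind == "inhale" and e.duration_s == pytest.approx(0.5)
                   for e in events)

    def test_short_runs_discarded_and_threshold_validated(self):
        classes = list(OTHER_ONLY)
        classes[10:12] = [int(FrameLabel.INHALE)] * 2     # 100 ms < 150 ms
        assert segment_breath_events(curves_of(classes)) == []
        with pytest.raises(ValueError):
            segment_breath_events(curves_of(OTHER_ONLY), threshold=1.5)

    def test_simulated_breath_count_matches_ground_truth(self, detector):
        """Detected inhale events match the synthesized count within ±1."""
        import dataclasses

        from sonostage.simulator import SimConfig

        cfg = dataclasses.replace(SimConfig(seed=5, night_epochs=20),
                                  nrem_breath_rate=12.0)
        enhanced, feats, labels, _ = make_stage_epoch("N", 5, cfg)
        curves = detector.predict_curves(feats)
        events = [e for e in segment_breath_events(curves, frame_feats=feats)
                  if e.kind == "inhale"]
        truth = np.sum(np.diff(np.r_[0, (labels == int(FrameLabel.INHALE))
                                     .astype(int)]) == 1)
        assert abs(len(events) - truth) <= 1


class TestWithinBreathing:
    def test_zero_events(self):
        curves = curves_of(OTHER_ONLY)
        feats = frame_features_matrix(
            np.zeros((FRAMES_PER_EPOCH, FRAME_SAMPLES), dtype=np.float32))
        v = within_breathing_features(None, curves, [], frame_feats=feats)
        assert v[0] == 0 and v[1] == 0                  # counts
        assert v[32] == 0.0                              # duty cycle
        assert np.isnan(v[2])                            # sentinel for durations

    def test_simulated_nrem_durations(self, detector):
        """12 breaths/min with 1.0-s inhales: recovered duration and duty."""
        import dataclasses

        from sonostage.simulator import SimConfig

        cfg = dataclasses.replace(SimConfig(seed=2, night_epochs=20),
                                  nrem_breath_rate=12.0)
        means, duties = [], []
        for seed in range(5):
            enhanced, feats, labels, _ = make_stage_epoch("N", 40 + seed, cfg)
            curves = detector.predict_curves(feats)
            events = segment_breath_events(curves, frame_feats=feats)
            v = within_breathing_features(enhanced, curves, events, feats)
            means.append(v[2])
            duties.append(v[32])
        assert np.nanmean(means) == pytest.approx(1.0, abs=0.2)
        assert np.mean(duties) >= 0.3

    def test_intensity_ratio_symmetric(self):
        classes = list(OTHER_ONLY)
        classes[100:120] = [int(FrameLabel.INHALE)] * 20
        classes[200:220] = [int(FrameLabel.EXHALE)] * 20
        curves = curves_of(classes)
        feats = np.zeros((FRAMES_PER_EPOCH, 17))
        feats[:, 0] = -40.0     # identical intensity everywhere
        events = segment_breath_events(curves, frame_feats=feats)
        v = within_breathing_features(None, curves, events, feats)
        assert v[12] == pytest.approx(1.0, abs=0.1)


class TestBetweenBreathing:
    def test_metronomic_breathing(self):
        """Breaths every 5 s: interval 5.0 ± 0.1 s, CV ≤ 0.05, dominant
        frequency 0.2 ± 0.02 Hz (closed-form expectations)."""
        classes = list(OTHER_ONLY)
        for start in range(0, FRAMES_PER_EPOCH, 100):   # 5-s period
            classes[start:start + 20] = [int(FrameLabel.INHALE)] * 20
        curves = curves_of(classes)
        events = segment_breath_events(curves)
        v = between_breathing_features(curves, events)
        names = list(BETWEEN_BREATHING_NAMES)
        assert v[names.index("bb_ibi_mean_s")] == pytest.approx(5.0, abs=0.1)
        assert v[names.index("bb_ibi_cv")] <= 0.05
        assert v[names.index("bb_dominant_freq_hz")] == pytest.approx(0.2, abs=0.02)

    def test_single_breath_imputed(self):
        classes = list(OTHER_ONLY)
        classes[50:70] = [int(FrameLabel.INHALE)] * 20
        curves = curves_of(classes)
        v = between_breathing_features(curves, segment_breath_events(curves))
        names = list(BETWEEN_BREATHING_NAMES)
        assert np.isnan(v[names.index("bb_ibi_mean_s")])
        assert v[names.index("bb_detectable_breathing_fraction")] > 0

    def test_rem_interval_cv_exceeds_nrem(self, detector, stage_epoch_bank):
        """Sign test over 20 seed pairs: REM breathing is more variable."""
        def cv(item):
            curves = item["curves"]
            v = between_breathing_features(
                curves, segment_breath_events(curves, frame_feats=item["feats"]))
            return v[list(BETWEEN_BREATHING_NAMES).index("bb_ibi_cv")]

        wins = 0
        for n_item, r_item in zip(stage_epoch_bank["N"][:20],
                                  stage_epoch_bank["R"][:20]):
            cn, cr = cv(n_item), cv(r_item)
            if np.isnan(cn) or np.isnan(cr):
                continue
            wins += cr > cn
        assert wins >= 14


class TestBodyMovement:
    def test_no_movement(self):
        v = body_movement_features(curves_of(OTHER_ONLY))
        names = list(BODY_MOVEMENT_NAMES)
        assert v[names.index("bm_event_count")] == 0
        assert v[names.index("bm_duration_fraction")] == 0.0
        assert v[names.index("bm_longest_free_run_frames")] == 600

    def test_single_centered_burst(self):
        classes = list(OTHER_ONLY)
        classes[280:320] = [int(FrameLabel.MOVEMENT)] * 40   # 2 s centered
        v = body_movement_features(curves_of(classes))
        names = list(BODY_MOVEMENT_NAMES)
        assert v[names.index("bm_event_count")] == 1
        assert v[names.index("bm_duration_fraction")] == pytest.approx(2 / 30)
        assert v[names.index("bm_dur_max_s")] == pytest.approx(2.0)

    def test_wake_moves_more_than_rem(self, stage_epoch_bank):
        counts = {}
        for stage in ("W", "R"):
            counts[stage] = np.mean([
                body_movement_features(item["curves"], item["feats"])[0]
                for item in stage_epoch_bank[stage]])
        assert counts["W"] > counts["R"]
        assert counts["R"] == pytest.approx(0.0, abs=0.1)


class TestBackgroundNoise:
    def test_silent_epoch_floors(self):
        feats = frame_features_matrix(
            np.zeros((FRAMES_PER_EPOCH, FRAME_SAMPLES), dtype=np.float32))
        v = background_noise_features(curves_of(OTHER_ONLY), feats,
                                      flat_profile(-80.0))
        names = list(BACKGROUND_NOISE_NAMES)
        assert v[names.index("bg_other_event_count")] == 0
        assert v[names.index("bg_other_intensity_max_dbfs")] == DB_FLOOR
        assert v[names.index("bg_noise_floor_delta_db")] == 0.0

    def test_door_slam_transient_detected(self):
        """A broadband 300-ms burst at −10 dBFS over a −45 dBFS floor."""
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((FRAMES_PER_EPOCH, FRAME_SAMPLES)
                                     ).astype(np.float32) * 10 ** (-45 / 20)
        burst = rng.standard_normal(6 * FRAME_SAMPLES).astype(np.float32)
        burst *= 10 ** (-10 / 20) / np.sqrt(np.mean(burst ** 2))
        frames[300:306] += burst.reshape(6, FRAME_SAMPLES)
        feats = frame_features_matrix(frames)
        classes = list(OTHER_ONLY)
        v = background_noise_features(curves_of(classes), feats,
                                      flat_profile(-45.0))
        names = list(BACKGROUND_NOISE_NAMES)
        assert v[names.index("bg_other_event_count")] >= 1
        assert v[names.index("bg_other_intensity_max_dbfs")] >= -15.0

    def test_noise_floor_delta_tracks_step(self):
        feats = np.zeros((FRAMES_PER_EPOCH, 17))
        v = background_noise_features(curves_of(OTHER_ONLY), feats,
                                      flat_profile(-35.0),
                                      prev_floor_dbfs=-45.0)
        names = list(BACKGROUND_NOISE_NAMES)
        assert v[names.index("bg_noise_floor_delta_db")] == pytest.approx(10.0, abs=0.5)


class TestPersonalization:
    def test_worked_example(self):
        v = personalization_features(SubjectMeta(age=18, gender=0, bmi=32), t=1)
        np.testing.assert_array_equal(v, [18.0, 0.0, 32.0, 1.0])

    def test_epoch_index_increments(self):
        meta = SubjectMeta(age=30, gender=1, bmi=25)
        assert personalization_features(meta, 7)[3] == 7.0
        assert personalization_features(meta, 8)[3] == 8.0

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError):
            SubjectMeta(age=30, gender=1, bmi=float("nan"))
        with pytest.raises(ValueError):
            personalization_features({"age": 30, "gender": 1, "bmi": None}, 1)
        with pytest.raises(ValueError):
            personalization_features(SubjectMeta(age=30, gender=1, bmi=25), 0)


class TestFullVector:
    def test_shape_determinism_and_finiteness(self, default_meta):
        enhanced, feats, labels, profile = make_stage_epoch("N", 0)
        curves = curves_of(OTHER_ONLY)
        v1 = extract_epoch_features(enhanced, curves, profile, default_meta, 3,
                                    frame_feats=feats)
        v2 = extract_epoch_features(enhanced, curves, profile, default_meta, 3,
                                    frame_feats=feats)
        assert v1.shape == (67,)
        np.testing.assert_array_equal(v1, v2)
        assert np.all(np.isfinite(v1))

    def test_silent_epoch_finite(self, default_meta):
        epoch = EpochAudio(np.zeros((FRAMES_PER_EPOCH, FRAME_SAMPLES)), 1)
        v = extract_epoch_features(epoch, curves_of(OTHER_ONLY),
                                   flat_profile(-80.0), default_meta, 1)
        assert np.all(np.isfinite(v))

    def test_linear_probe_separates_stages(self, detector, stage_epoch_bank,
                                           default_meta):
        """A linear probe on the 67 features tells W/R/N apart (>= 80%)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        X, y = [], []
        for si, stage in enumerate(("W", "R", "N")):
            for item in stage_epoch_bank[stage]:
                v = extract_epoch_features(
                    item["epoch"], item["curves"], item["profile"],
                    default_meta, 100, frame_feats=item["feats"])
                X.append(v)
                y.append(si)
        X = np.asarray(X)
        X = (X - X.mean(0)) / (X.std(0) + 1e-9)
        scores = cross_val_score(LogisticRegression(max_iter=500), X, y, cv=5)
        assert scores.mean() >= 0.8


def test_feature_matrix_csv_and_manifest(tmp_path):
    import json

    from sonostage.features import registry_hash, write_feature_matrix

    X = np.random.default_rng(0).normal(size=(4, N_FEATURES))
    path = tmp_path / "night.csv"
    write_feature_matrix(X, path)
    lines = path.read_text().splitlines()
    assert lines[0].split(",")[1] == FEATURE_NAMES[0]
    assert len(lines) == 5
    manifest = json.loads((tmp_path / "night.csv.registry.json").read_text())
    assert manifest["registry_hash"] == registry_hash()
    assert manifest["families"]["within_breathing"] == 33
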