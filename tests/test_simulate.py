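import numpy as np
import pytest
from dataclasses import replace

from oculaff.annotation import annotate_table
from oculaff.events import ivt_segment
from oculaff.pipeline import feature_table
from oculaff.preprocess import preprocess
from oculaff.reference import CLASS_FEATURE_MEANS
from oculaff.screening import fit_feature_mlm
from oculaff.simulate import (class_profile, generate_recording, generate_session,
                              luminance_probe)


class TestProfiles:
    def test_level_profiles_take_published_targets(self):
        for cls in ("LA", "MA", "HA", "NV", "MV", "PV"):
            p = class_profile(cls)
            m = CLASS_FEATURE_MEANS[cls]
            assert p.fix_duration_median_ms == m["fix_duration_median"]
            assert p.blink_rate_hz == m["blink_freq"]
            assert p.pupil_mean_mm == m["pupil_diameter_mean"]

    def test_quadrant_profiles_average_parents(self):
        q = class_profile("HANV")
        ha, nv = CLASS_FEATURE_MEANS["HA"], CLASS_FEATURE_MEANS["NV"]
        assert q.pupil_mean_mm == pytest.approx(
            (ha["pupil_diameter_mean"] + nv["pupil_diameter_mean"]) / 2)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            class_profile("XX")


class TestGenerateRecording:
    def test_same_seed_is_bitwise_identical(self):
        prof = class_profile("HA")
        r1, g1 = generate_recording(prof, duration_s=5.0, seed=42)
        r2, g2 = generate_recording(prof, duration_s=5.0, seed=42)
        for attr in ("t", "gaze_x", "gaze_y", "pupil_mm", "confidence"):
            np.testing.assert_array_equal(getattr(r1, attr), getattr(r2, attr))
        assert r1.blinks == r2.blinks
        assert len(g1.fixations) == len(g2.fixations)

    def test_zero_blink_rate_emits_no_blinks(self):
        prof = replace(class_profile("LA"), blink_rate_hz=0.0)
        rec, gt = generate_recording(prof, duration_s=10.0, seed=0)
        assert rec.blinks == [] and gt.blinks == []

    def test_stream_is_on_screen_and_well_formed(self, ha_recording):
        rec, gt = ha_recording
        assert rec.n_samples == 60 * 240 + 1
        on = np.isfinite(rec.gaze_x)
        assert ((rec.gaze_x[on] >= 0) & (rec.gaze_x[on] <= 1)).all()
        assert ((rec.gaze_y[on] >= 0) & (rec.gaze_y[on] <= 1)).all()
        assert np.isnan(rec.pupil_mm).sum() > 0  # blinks lose the pupil
        valid_pupil = rec.pupil_mm[np.isfinite(rec.pupil_mm)]
        assert (valid_pupil > 1.0).all() and (valid_pupil < 9.0).all()

    def test_fixation_speeds_stay_below_threshold(self, ha_recording):
        rec, gt = ha_recording
        series = preprocess(rec)
        for f in gt.fixations:
            inner = (series.t[:-1] >= f.start_s + 2 / rec.fs_hz) & \
                    (series.t[:-1] <= f.end_s - 2 / rec.fs_hz)
            sp = series.speed[inner]
            sp = sp[np.isfinite(sp)]
            if len(sp):
                assert sp.max() < 45.0

    def test_noiseless_counts_and_boundaries_recovered(self, noiseless_recording):
        rec, gt = noiseless_recording
        ev = ivt_segment(preprocess(rec))
        assert len(ev.fixations) == len(gt.fixations)
        assert len(ev.saccades) == len(gt.saccades)
        tol = 1.0 / rec.fs_hz + 1e-9
        for det, true in zip(ev.fixations, gt.fixations):
            assert abs(det.start_s - true.start_s) <= tol
            assert abs(det.end_s - true.end_s) <= tol
        for det, true in zip(ev.saccades, gt.saccades):
            assert abs(det.start_s - true.start_s) <= tol
            assert abs(det.end_s - true.end_s) <= tol

    def test_ground_truth_tiles_the_recording(self, noiseless_recording):
        rec, gt = noiseless_recording
        events = sorted(
            [(f.start_s, f.end_s) for f in gt.fixations]
            + [(s.start_s, s.end_s) for s in gt.saccades]
            + [(b.start_s, b.end_s) for b in gt.blinks])
        assert events[0][0] == rec.t[0]
        for (s1, e1), (s2, e2) in zip(events, events[1:]):
            assert s2 - e1 <= 2.5 / rec.fs_hz + 1e-9  # hold samples only
        assert rec.t[-1] - events[-1][1] <= 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_recording(class_profile("LA"), duration_s=0.0)


class TestGenerateSession:
    def test_layout_two_participants_twenty_recordings(self):
        sess = generate_session(2, seed=0, duration_s=2.0)
        assert len(sess.recordings) == 20
        assert len(sess.manifest) == 20
        assert sess.manifest["emotion"].value_counts().to_dict() == {
            "anger": 4, "tenderness": 4, "neutral": 4, "disgust": 4, "sadness": 4}
        assert sess.manifest.duplicated(["participant_id", "video_id"]).sum() == 0

    def test_zero_rating_noise_reproduces_objective_labels(self):
        sess = generate_session(2, seed=1, duration_s=2.0, rating_noise_sd=0.0)
        table = annotate_table(sess.ratings, sess.manifest)
        assert (table["subjective_emotion"] == table["objective_emotion"]).all()

    def test_zero_participant_offsets_give_null_random_variance(self):
        sess = generate_session(6, seed=2, duration_s=4.0, participant_cv=0.0)
        feats = feature_table(sess.recordings)
        table = annotate_table(sess.ratings, sess.manifest).set_index(
            ["participant_id", "video_id"])
        merged = feats.join(table)
        res = fit_feature_mlm(merged["pupil_diameter_mean"], merged["arousal"],
                              merged.index.get_level_values(0))
        assert res.random_intercept_var < 0.003 or res.fixed_effects_fallback

    def test_participant_offsets_create_random_variance(self):
        sess = generate_session(8, seed=3, duration_s=4.0, participant_cv=0.12)
        feats = feature_table(sess.recordings)
        pid = feats.index.get_level_values(0)
        labels = ["A", "B"] * (len(feats) // 2)
        res = fit_feature_mlm(feats["pupil_diameter_mean"], labels, pid)
        assert res.random_intercept_var > 0.01


def test_luminance_probe_shape():
    rec, _ = generate_recording(class_profile("MAMV"), duration_s=10.0, seed=9)
    v = luminance_probe(rec, coupling=0.0, frame_rate_hz=25.0, seed=1)
    assert len(v) == int(np.floor(rec.duration_s * 25)) + 1
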