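import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculaff.recordings import (EmptyRecordingError, RawRecording, RecordingFormatError,
                                ScreenGeometry, merge_intervals, read_recording,
                                validity_filter, write_recording)
from oculaff.simulate import class_profile, generate_recording


def _write_gaze(path, rows, columns=("timestamp_s", "gaze_x_norm", "gaze_y_norm",
                                     "pupil_mm", "confidence")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)


class TestReadRecording:
    def test_toy_file_identity_readback(self, tmp_path):
        rows = [(0.0, 0.5, 0.5, 3.2, 1.0), (0.1, 0.6, 0.4, 3.3, 0.9),
                (0.2, 0.55, 0.45, 3.25, 0.95)]
        _write_gaze(tmp_path / "g.csv", rows)
        rec = read_recording(tmp_path / "g.csv")
        assert rec.n_samples == 3
        np.testing.assert_allclose(rec.t, [0.0, 0.1, 0.2])
        np.testing.assert_allclose(rec.pupil_mm, [3.2, 3.3, 3.25])

    def test_header_driven_parsing_is_column_order_invariant(self, tmp_path):
        rows = [(0.0, 0.5, 0.5, 3.2, 1.0), (0.1, 0.6, 0.4, 3.3, 0.9)]
        _write_gaze(tmp_path / "a.csv", rows)
        permuted = [(r[4], r[0], r[3], r[1], r[2]) for r in rows]
        _write_gaze(tmp_path / "b.csv", permuted,
                    columns=("confidence", "timestamp_s", "pupil_mm",
                             "gaze_x_norm", "gaze_y_norm"))
        a, b = read_recording(tmp_path / "a.csv"), read_recording(tmp_path / "b.csv")
        for attr in ("t", "gaze_x", "gaze_y", "pupil_mm", "confidence"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_round_trip_preserves_numeric_content(self, tmp_path):
        rec, _ = generate_recording(class_profile("MAMV"), duration_s=3.0, seed=5)
        write_recording(rec, tmp_path / "g.csv", tmp_path / "b.csv")
        back = read_recording(tmp_path / "g.csv", tmp_path / "b.csv",
                              meta={"participant_id": rec.participant_id,
                                    "video_id": rec.video_id,
                                    "duration_s": rec.clip_duration_s})
        for attr in ("t", "gaze_x", "gaze_y", "pupil_mm", "confidence"):
            np.testing.assert_array_equal(getattr(rec, attr), getattr(back, attr))
        assert back.blinks == pytest.approx(rec.blinks)

    def test_missing_column_raises_format_error(self, tmp_path):
        pd.DataFrame({"timestamp_s": [0, 1], "gaze_x_norm": [0.5, 0.5]}).to_csv(
            tmp_path / "g.csv", index=False)
        with pytest.raises(RecordingFormatError):
            read_recording(tmp_path / "g.csv")

    def test_too_few_samples_raises(self, tmp_path):
        _write_gaze(tmp_path / "g.csv", [(0.0, 0.5, 0.5, 3.0, 1.0)])
        with pytest.raises(EmptyRecordingError):
            read_recording(tmp_path / "g.csv")


def _flat_recording(clip_s=10.0, n=2401, blinks=(), gaze_x=0.5, aborted=False,
                    offscreen_first=0):
    t = np.arange(n) / 240.0
    gx = np.full(n, gaze_x)
    if offscreen_first:
        gx[:offscreen_first] = 1.5
    return RawRecording(participant_id="p", video_id="v", fs_hz=240.0, t=t,
                        gaze_x=gx, gaze_y=np.full(n, 0.5),
                        pupil_mm=np.full(n, 3.5), confidence=np.ones(n),
                        blinks=list(blinks), aborted=aborted, clip_duration_s=clip_s)


class TestValidityFilter:
    def test_clean_recording_is_kept(self):
        rep = validity_filter(_flat_recording())
        assert rep.verdict == "kept" and rep.reasons == ()

    def test_eye_closure_over_ten_percent_excludes(self):
        rep = validity_filter(_flat_recording(blinks=[(1.0, 2.5)]))  # 15% of 10 s
        assert rep.verdict == "excluded"
        assert any("eye-closure" in r for r in rep.reasons)
        assert rep.eyes_closed_fraction == pytest.approx(0.15)

    def test_offscreen_over_twenty_percent_excludes(self):
        rep = validity_filter(_flat_recording(offscreen_first=600))  # 25% of 10 s
        assert rep.verdict == "excluded"
        assert any("off-screen" in r for r in rep.reasons)
        assert rep.offscreen_fraction == pytest.approx(0.25)

    def test_aborted_recording_excluded(self):
        rep = validity_filter(_flat_recording(aborted=True))
        assert rep.verdict == "excluded" and "aborted playback" in rep.reasons

    def test_boundary_values_are_kept(self):
        # criteria are strictly "longer than": exactly 10% closure is kept
        rep = validity_filter(_flat_recording(blinks=[(1.0, 2.0)]))
        assert rep.eyes_closed_fraction == pytest.approx(0.10)
        assert rep.verdict == "kept"

    def test_filter_conservation_and_monotonicity(self):
        closures = [0.0, 0.05, 0.09, 0.11, 0.2, 0.5]
        recs = [_flat_recording(blinks=[(0.0, 10.0 * c)] if c else []) for c in closures]
        reports = [validity_filter(r) for r in recs]
        assert len(reports) == len(recs)  # each recording gets exactly one verdict
        verdicts = [r.verdict for r in reports]
        # increasing closure can only flip kept -> excluded
        assert verdicts == sorted(verdicts, key=lambda v: v == "excluded")

    def test_missing_clip_duration_is_configuration_error(self):
        rec = _flat_recording()
        rec.clip_duration_s = None
        with pytest.raises(ValueError):
            validity_filter(rec)


@given(st.lists(st.tuples(st.floats(0, 100, allow_nan=False),
                          st.floats(0, 100, allow_nan=False)), max_size=20))
@settings(deadline=None, max_examples=50)
def test_merge_intervals_is_disjoint_and_covers(intervals):
    intervals = [(min(a, b), max(a, b)) for a, b in intervals if a != b]
    merged = merge_intervals(intervals)
    # pairwise disjoint and sorted
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        assert e1 < s2
    # total coverage equals the measure of the union
    grid = np.linspace(0, 100, 2001)
    in_raw = np.zeros(len(grid), bool)
    in_merged = np.zeros(len(grid), bool)
    for s, e in intervals:
        in_raw |= (grid >= s) & (grid <= e)
    for s, e in merged:
        in_merged |= (grid >= s) & (grid <= e)
    assert (in_raw == in_merged).all()


def test_screen_geometry_rejects_nonpositive():
    with pytest.raises(ValueError):
        ScreenGeometry(width_mm=-1)


def test_load_esee_d_missing_directory_names_accession(tmp_path):
    from oculaff.recordings import load_esee_d
    with pytest.raises(FileNotFoundError, match="10.5281/zenodo.5775674"):
        load_esee_d(tmp_path / "nope")
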