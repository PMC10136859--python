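"""Recording data model, CSV I/O, and recording-validity filtering.

A recording is one participant watching one video clip on a 240 Hz
binocular eye tracker: timestamps, normalized gaze coordinates, pupil
diameter in millimetres, a per-sample detection confidence, plus a list of
blink intervals reported by the tracker.

Validity filtering removes recordings in which the participant effectively
did not watch the clip: eyes closed for more than 10% of the clip, gaze
decoupled from the screen (off-screen / low confidence outside blinks, used
here as a mind-wandering proxy) for more than 20% of the clip, or playback
aborted by the participant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GAZE_COLUMNS = ["timestamp_s", "gaze_x_norm", "gaze_y_norm", "pupil_mm", "confidence"]
BLINK_COLUMNS = ["start_s", "end_s"]
MANIFEST_COLUMNS = ["participant_id", "video_id", "emotion", "duration_s"]
RATING_COLUMNS = ["participant_id", "video_id", "anger", "disgust", "sadness", "tenderness"]

EMOTIONS = ("anger", "disgust", "sadness", "tenderness", "neutral")

#: Session manifest: a DataFrame with one row per (participant_id, video_id)
#: carrying the objective emotion and clip duration; see :func:`read_manifest`.
SessionManifest = pd.DataFrame

ESEE_D_ACCESSION = "10.5281/zenodo.5775674"


class RecordingFormatError(ValueError):
    """A recording file does not conform to the documented schema."""


class EmptyRecordingError(ValueError):
    """Fewer than 2 valid samples remain after parsing."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry and viewing distance.

    Defaults correspond to the acquisition setup emulated throughout the
    package: a 24-inch 16:9 display at 1280x720 viewed from 80 cm.
    """

    width_mm: float = 531.3
    height_mm: float = 298.9
    res_x: int = 1280
    res_y: int = 720
    distance_mm: float = 800.0

    def __post_init__(self):
        for name in ("width_mm", "height_mm", "res_x", "res_y", "distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")

    @property
    def half_extent_deg(self) -> tuple[float, float]:
        """Angular half-extent of the screen (x, y) in degrees."""
        hx = math.degrees(math.atan2(self.width_mm / 2, self.distance_mm))
        hy = math.degrees(math.atan2(self.height_mm / 2, self.distance_mm))
        return hx, hy


@dataclass
class RawRecording:
    """One participant x video eye-tracker sample stream.

    Gaze coordinates are normalized to the screen (origin bottom-left,
    x rightward, y upward; on-screen samples lie in [0, 1]^2).  Timestamps
    are seconds from recording start and must be nondecreasing; irregular
    sampling is tolerated, ``fs_hz`` is the nominal rate.
    """

    participant_id: str
    video_id: str
    fs_hz: float
    t: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil_mm: np.ndarray
    confidence: np.ndarray
    blinks: list[tuple[float, float]] = field(default_factory=list)
    aborted: bool = False
    clip_duration_s: float | None = None

    def __post_init__(self):
        arrays = {}
        for name in ("t", "gaze_x", "gaze_y", "pupil_mm", "confidence"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = len(self.t)
        if n < 2:
            raise EmptyRecordingError(f"recording needs >= 2 samples, got {n}")
        if any(len(a) != n for a in arrays.values()):
            raise ValueError("t, gaze_x, gaze_y, pupil_mm, confidence must share length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be nondecreasing")
        self.blinks = merge_intervals(self.blinks)
        t0, t1 = float(self.t[0]), float(self.t[-1])
        for s, e in self.blinks:
            if s < t0 - 1e-9 or e > t1 + 1e-9:
                raise ValueError(f"blink interval ({s}, {e}) outside recording span")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of the recording-validity filter for one recording."""

    participant_id: str
    video_id: str
    eyes_closed_fraction: float
    offscreen_fraction: float
    aborted: bool
    verdict: str  # "kept" | "excluded"
    reasons: tuple[str, ...]


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Merge overlapping or touching (start, end) intervals; drops empties."""
    ivals = sorted((float(s), float(e)) for s, e in intervals if e > s)
    merged: list[list[float]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"{path}: missing required column(s) {missing}")


def read_recording(gaze_path, blink_path=None, meta: dict | None = None,
                   fs_hz: float = 240.0) -> RawRecording:
    """Read one recording from the documented CSV schemas.

    Parameters
    ----------
    gaze_path : path to CSV with columns ``timestamp_s, gaze_x_norm,
        gaze_y_norm, pupil_mm, confidence`` (header required, any order).
    blink_path : optional path to CSV with columns ``start_s, end_s``.
    meta : optional manifest row with keys ``participant_id, video_id,
        emotion, duration_s, aborted``.

    Rows whose timestamp cannot be parsed are dropped and counted in the
    log; non-finite gaze/pupil values are kept as NaN (they are masked
    downstream, not errors).
    """
    meta = dict(meta or {})
    df = pd.read_csv(gaze_path, float_precision="round_trip")
    _require_columns(df, GAZE_COLUMNS, gaze_path)
    df = df[GAZE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = df["timestamp_s"].isna()
    if bad.any():
        log.warning("%s: dropped %d rows with unparseable timestamps", gaze_path, int(bad.sum()))
        df = df[~bad]
    if len(df) < 2:
        raise EmptyRecordingError(f"{gaze_path}: fewer than 2 valid samples")

    blinks: list[tuple[float, float]] = []
    if blink_path is not None and Path(blink_path).exists():
        bdf = pd.read_csv(blink_path, float_precision="round_trip")
        _require_columns(bdf, BLINK_COLUMNS, blink_path)
        blinks = list(zip(bdf["start_s"].astype(float), bdf["end_s"].astype(float)))
        # clip to the recording span so the type invariant holds
        t0, t1 = float(df["timestamp_s"].iloc[0]), float(df["timestamp_s"].iloc[-1])
        blinks = [(max(s, t0), min(e, t1)) for s, e in blinks if min(e, t1) > max(s, t0)]

    return RawRecording(
        participant_id=str(meta.get("participant_id", "unknown")),
        video_id=str(meta.get("video_id", Path(str(gaze_path)).stem)),
        fs_hz=float(meta.get("fs_hz", fs_hz)),
        t=df["timestamp_s"].to_numpy(),
        gaze_x=df["gaze_x_norm"].to_numpy(),
        gaze_y=df["gaze_y_norm"].to_numpy(),
        pupil_mm=df["pupil_mm"].to_numpy(),
        confidence=df["confidence"].to_numpy(),
        blinks=blinks,
        aborted=bool(meta.get("aborted", False)),
        clip_duration_s=(float(meta["duration_s"]) if "duration_s" in meta else None),
    )


def write_recording(rec: RawRecording, gaze_path, blink_path=None) -> None:
    """Write a recording back to the CSV schemas ``read_recording`` reads."""
    pd.DataFrame({
        "timestamp_s": rec.t,
        "gaze_x_norm": rec.gaze_x,
        "gaze_y_norm": rec.gaze_y,
        "pupil_mm": rec.pupil_mm,
        "confidence": rec.confidence,
    }).to_csv(gaze_path, index=False, float_format="%.17g")
    if blink_path is not None:
        pd.DataFrame(rec.blinks, columns=BLINK_COLUMNS).to_csv(blink_path, index=False,
                                                               float_format="%.17g")


def read_manifest(path) -> pd.DataFrame:
    """Read the session manifest; validates uniqueness and emotion labels."""
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, path)
    dup = df.duplicated(subset=["participant_id", "video_id"])
    if dup.any():
        raise RecordingFormatError(f"{path}: duplicate (participant_id, video_id) rows")
    bad = set(df["emotion"]) - set(EMOTIONS)
    if bad:
        raise RecordingFormatError(f"{path}: unknown emotion label(s) {sorted(bad)}")
    return df


def _occupied_fraction(intervals, window: tuple[float, float], total: float) -> float:
    lo, hi = window
    covered = sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in merge_intervals(intervals))
    return min(1.0, covered / total)


def validity_filter(rec: RawRecording, blink_confidence_threshold: float = 0.5,
                    eyes_closed_max: float = 0.10, offscreen_max: float = 0.20) -> ValidityReport:
    """Apply the recording-validity criteria.

    A recording is excluded iff eyes-closed time exceeds 10% of the clip
    duration, the off-screen (mind-wandering proxy) fraction exceeds 20%,
    or playback was aborted.  Boundary values exactly at the cut are kept
    (the criteria are strictly "longer than").

    Eyes-closed time is the union of tracker blink intervals and contiguous
    low-confidence runs.  The off-screen fraction counts samples with gaze
    outside [0, 1]^2 (or confidence below the blink threshold) that are not
    inside an eyes-closed interval.
    """
    if rec.clip_duration_s is None or rec.clip_duration_s <= 0:
        raise ValueError("validity_filter requires a positive clip_duration_s")
    total = float(rec.clip_duration_s)
    window = (float(rec.t[0]), float(rec.t[0]) + total)

    # eyes-closed = tracker blinks U contiguous low-confidence runs
    closed = list(rec.blinks)
    low = rec.confidence < blink_confidence_threshold
    for s_idx, e_idx in _runs(low):
        closed.append((float(rec.t[s_idx]), float(rec.t[min(e_idx, rec.n_samples - 1)])))
    closed = merge_intervals(closed)
    eyes_closed_fraction = _occupied_fraction(closed, window, total)

    # off-screen proxy, outside the eyes-closed intervals
    in_closed = np.zeros(rec.n_samples, dtype=bool)
    for s, e in closed:
        in_closed |= (rec.t >= s) & (rec.t <= e)
    offscreen = (
        (rec.gaze_x < 0) | (rec.gaze_x > 1) | (rec.gaze_y < 0) | (rec.gaze_y > 1)
        | ~np.isfinite(rec.gaze_x) | ~np.isfinite(rec.gaze_y)
    ) & ~in_closed
    # fraction of clip time, approximated by sample share of the nominal duration
    offscreen_fraction = min(1.0, float(offscreen.sum()) / rec.fs_hz / total)

    reasons = []
    if eyes_closed_fraction > eyes_closed_max:
        reasons.append(f"eye-closure > {eyes_closed_max:.0%}")
    if offscreen_fraction > offscreen_max:
        reasons.append(f"off-screen > {offscreen_max:.0%}")
    if rec.aborted:
        reasons.append("aborted playback")
    return ValidityReport(
        participant_id=rec.participant_id,
        video_id=rec.video_id,
        eyes_closed_fraction=eyes_closed_fraction,
        offscreen_fraction=offscreen_fraction,
        aborted=rec.aborted,
        verdict="excluded" if reasons else "kept",
        reasons=tuple(reasons),
    )


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs (stop exclusive)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


def load_esee_d(root) -> tuple[list[RawRecording], pd.DataFrame, pd.DataFrame]:
    """Load a local copy of the deposited eSEE-d archive.

    Expects ``root`` to contain ``manifest.csv``, ``ratings.csv`` and per
    recording ``<participant>_<video>_gaze.csv`` / ``..._blinks.csv`` files
    in the package CSV schemas.  Never required by the test suite.

    Returns (recordings, manifest, ratings).
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(
            f"eSEE-d dataset not present at {root}; download accession "
            f"{ESEE_D_ACCESSION} and point --data-dir at the extracted archive"
        )
    manifest = read_manifest(root / "manifest.csv")
    ratings = pd.read_csv(root / "ratings.csv")
    _require_columns(ratings, RATING_COLUMNS, root / "ratings.csv")
    recordings = []
    for row in manifest.to_dict("records"):
        stem = f"{row['participant_id']}_{row['video_id']}"
        gaze = root / f"{stem}_gaze.csv"
        if not gaze.exists():
            log.warning("missing gaze file %s; skipped", gaze)
            continue
        recordings.append(read_recording(gaze, root / f"{stem}_blinks.csv", meta=row))
    return recordings, manifest, ratings
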