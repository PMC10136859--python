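"""Oculomotor event detection: I-VT fixation/saccade segmentation and blinks.

The velocity-threshold identification (I-VT) algorithm labels every speed
sample strictly below the velocity threshold as a fixation point and every
other sample as a saccade point, collapses consecutive fixation points into
groups, discards groups shorter than the minimum fixation duration, and
maps each surviving group to a fixation at the centroid of its points.
Maximal runs of saccade points become saccades with duration, endpoint
amplitude, and mean/peak velocity.

Defaults: 45 deg/s velocity threshold, 55 ms minimum fixation duration,
0.5 confidence threshold for blink assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .preprocess import AngularGazeSeries, angular_distance_deg
from .recordings import RawRecording, merge_intervals, _runs


@dataclass(frozen=True)
class EventDetectorConfig:
    """Thresholds for event detection."""

    velocity_threshold_deg_s: float = 45.0
    min_fixation_ms: float = 55.0
    blink_confidence_threshold: float = 0.5

    def __post_init__(self):
        for name in ("velocity_threshold_deg_s", "min_fixation_ms", "blink_confidence_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EventDetectorConfig.{name} must be positive")


@dataclass(frozen=True)
class Fixation:
    start_s: float
    end_s: float
    duration_ms: float
    centroid_x_deg: float
    centroid_y_deg: float


@dataclass(frozen=True)
class Saccade:
    start_s: float
    end_s: float
    duration_ms: float
    amplitude_deg: float
    mean_velocity_deg_s: float
    peak_velocity_deg_s: float


@dataclass(frozen=True)
class Blink:
    start_s: float
    end_s: float
    duration_ms: float


@dataclass
class OculomotorEvents:
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)
    recording_duration_s: float = 0.0


FIXATION_POINT, SACCADE_POINT, INVALID_POINT = 0, 1, -1


def label_speed_samples(speed: np.ndarray, velocity_threshold_deg_s: float) -> np.ndarray:
    """Per-interval I-VT labels: 0 fixation, 1 saccade, -1 invalid (NaN).

    A speed exactly at the threshold is a saccade point (the fixation rule
    is strictly below).
    """
    speed = np.asarray(speed, dtype=float)
    labels = np.full(speed.shape, INVALID_POINT, dtype=int)
    finite = np.isfinite(speed)
    labels[finite & (speed < velocity_threshold_deg_s)] = FIXATION_POINT
    labels[finite & (speed >= velocity_threshold_deg_s)] = SACCADE_POINT
    return labels


def ivt_segment(series: AngularGazeSeries,
                cfg: EventDetectorConfig | None = None) -> OculomotorEvents:
    """Segment an angular gaze series into fixations and saccades.

    Speed index ``i`` describes the interval (t[i], t[i+1]]; a run of
    intervals [a, b] therefore spans samples a..b+1 in time.  Fixation
    groups shorter than the minimum duration are discarded as unclassified
    gaps (not merged into adjacent saccades).
    """
    cfg = cfg or EventDetectorConfig()
    if series.speed is None:
        raise ValueError("series has no speed; run the preprocessing chain first")
    events = OculomotorEvents(recording_duration_s=float(series.t[-1] - series.t[0]))
    labels = label_speed_samples(series.speed, cfg.velocity_threshold_deg_s)

    for a, b_excl in _runs(labels == FIXATION_POINT):
        b = b_excl - 1  # inclusive last interval index
        start, end = float(series.t[a]), float(series.t[b + 1])
        duration_ms = (end - start) * 1000.0
        if duration_ms < cfg.min_fixation_ms:
            continue
        sl = slice(a, b + 2)  # samples a..b+1
        events.fixations.append(Fixation(
            start_s=start, end_s=end, duration_ms=duration_ms,
            centroid_x_deg=float(np.mean(series.theta_x[sl])),
            centroid_y_deg=float(np.mean(series.theta_y[sl])),
        ))

    for a, b_excl in _runs(labels == SACCADE_POINT):
        b = b_excl - 1
        start, end = float(series.t[a]), float(series.t[b + 1])
        amp = float(angular_distance_deg(series.theta_x[a], series.theta_y[a],
                                         series.theta_x[b + 1], series.theta_y[b + 1]))
        run_speed = series.speed[a:b + 1]
        events.saccades.append(Saccade(
            start_s=start, end_s=end, duration_ms=(end - start) * 1000.0,
            amplitude_deg=amp,
            mean_velocity_deg_s=float(np.mean(run_speed)),
            peak_velocity_deg_s=float(np.max(run_speed)),
        ))
    return events


def assemble_blinks(rec: RawRecording,
                    cfg: EventDetectorConfig | None = None) -> list[Blink]:
    """Assemble blink events for a recording.

    Tracker-provided blink intervals are used when present; otherwise
    blinks are derived as maximal runs of samples whose confidence falls
    below the blink confidence threshold.  Overlapping or touching
    intervals are merged.
    """
    cfg = cfg or EventDetectorConfig()
    if rec.blinks:
        intervals = rec.blinks
    else:
        low = rec.confidence < cfg.blink_confidence_threshold
        intervals = [(float(rec.t[s]), float(rec.t[min(e, rec.n_samples - 1)]))
                     for s, e in _runs(low)]
    return [Blink(start_s=s, end_s=e, duration_ms=(e - s) * 1000.0)
            for s, e in merge_intervals(intervals) if e > s]


class IVTEventDetector(BaseEstimator):
    """Velocity-threshold event detector with scikit-learn style parameters.

    A stateless transformer-like object: ``transform`` maps
    (AngularGazeSeries, RawRecording) pairs to :class:`OculomotorEvents`.
    ``ivt_segment`` and ``assemble_blinks`` are the functional equivalents.
    """

    def __init__(self, velocity_threshold_deg_s: float = 45.0,
                 min_fixation_ms: float = 55.0,
                 blink_confidence_threshold: float = 0.5):
        self.velocity_threshold_deg_s = velocity_threshold_deg_s
        self.min_fixation_ms = min_fixation_ms
        self.blink_confidence_threshold = blink_confidence_threshold

    def _config(self) -> EventDetectorConfig:
        return EventDetectorConfig(
            velocity_threshold_deg_s=self.velocity_threshold_deg_s,
            min_fixation_ms=self.min_fixation_ms,
            blink_confidence_threshold=self.blink_confidence_threshold,
        )

    def fit(self, X=None, y=None):
        return self

    def detect(self, series: AngularGazeSeries,
               rec: RawRecording | None = None) -> OculomotorEvents:
        cfg = self._config()
        events = ivt_segment(series, cfg)
        if rec is not None:
            events.blinks = assemble_blinks(rec, cfg)
        return events

    def transform(self, X):
        """X: iterable of (series, recording) pairs -> list of events."""
        return [self.detect(series, rec) for series, rec in X]
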