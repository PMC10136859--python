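"""Gaze preprocessing: visual-angle conversion, angular velocity, denoising.

Normalized screen coordinates are converted to degrees of visual angle
relative to the screen-center normal, sample-to-sample angular speed is
computed from the exact 3-D gaze directions, and the speed series is
denoised with a 5-tap FIR smoothing filter (uniform moving average by
default, kernel configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import RawRecording, ScreenGeometry

DEFAULT_KERNEL = (0.2, 0.2, 0.2, 0.2, 0.2)


@dataclass
class AngularGazeSeries:
    """Gaze in degrees of visual angle with per-interval angular speed.

    ``speed`` has length ``n - 1``; ``speed[i]`` is the angular velocity over
    the interval (t[i], t[i+1]], i.e. aligned to the trailing sample.
    ``valid`` marks samples usable for event detection (on-screen, finite,
    confident, outside blinks).
    """

    t: np.ndarray
    theta_x: np.ndarray
    theta_y: np.ndarray
    valid: np.ndarray
    speed: np.ndarray | None = None
    fs_hz: float = 240.0

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def pair_valid(self) -> np.ndarray:
        """Validity of each speed interval: both endpoint samples valid."""
        return self.valid[:-1] & self.valid[1:]


def to_visual_angle(rec: RawRecording, geom: ScreenGeometry | None = None,
                    confidence_threshold: float = 0.5,
                    mask_blinks: bool = True) -> AngularGazeSeries:
    """Convert normalized gaze to degrees of visual angle.

    Per axis, ``theta = atan(offset_from_screen_center / viewing_distance)``
    with the eye assumed on the screen-center normal.  Samples that are
    off-screen, non-finite, below the confidence threshold, or inside a
    tracker blink interval are masked as invalid (but still converted where
    finite).
    """
    geom = geom or ScreenGeometry()
    dx_mm = (rec.gaze_x - 0.5) * geom.width_mm
    dy_mm = (rec.gaze_y - 0.5) * geom.height_mm
    theta_x = np.degrees(np.arctan2(dx_mm, geom.distance_mm))
    theta_y = np.degrees(np.arctan2(dy_mm, geom.distance_mm))

    valid = (
        np.isfinite(rec.gaze_x) & np.isfinite(rec.gaze_y)
        & (rec.gaze_x >= 0) & (rec.gaze_x <= 1)
        & (rec.gaze_y >= 0) & (rec.gaze_y <= 1)
        & (rec.confidence >= confidence_threshold)
    )
    if mask_blinks:
        for s, e in rec.blinks:
            valid &= ~((rec.t >= s) & (rec.t <= e))
    return AngularGazeSeries(t=rec.t.copy(), theta_x=theta_x, theta_y=theta_y,
                             valid=valid, fs_hz=rec.fs_hz)


def _direction_vectors(theta_x: np.ndarray, theta_y: np.ndarray) -> np.ndarray:
    """Unit 3-D gaze direction for per-axis angles (tangent construction)."""
    v = np.stack([np.tan(np.radians(theta_x)), np.tan(np.radians(theta_y)),
                  np.ones_like(theta_x)], axis=-1)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def angular_distance_deg(theta_x1, theta_y1, theta_x2, theta_y2) -> np.ndarray:
    """Great angle (degrees) between two gaze directions given per-axis angles.

    Exact on the 3-D gaze vectors; for small separations this approaches the
    Euclidean distance in the (theta_x, theta_y) plane.
    """
    v1 = _direction_vectors(np.asarray(theta_x1, float), np.asarray(theta_y1, float))
    v2 = _direction_vectors(np.asarray(theta_x2, float), np.asarray(theta_y2, float))
    dots = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def angular_velocity(series: AngularGazeSeries) -> AngularGazeSeries:
    """Compute sample-to-sample angular speed (deg/s) in place and return.

    ``speed[i]`` is the great angle between consecutive gaze directions
    divided by the time step.  Intervals spanning an invalid sample are NaN.
    """
    if series.n_samples < 2:
        raise ValueError("angular velocity needs >= 2 samples")
    dt = np.diff(series.t)
    if np.any(dt <= 0):
        raise ValueError("nonpositive time step in series")
    sep = angular_distance_deg(series.theta_x[:-1], series.theta_y[:-1],
                               series.theta_x[1:], series.theta_y[1:])
    speed = sep / dt
    speed[~series.pair_valid()] = np.nan
    series.speed = speed
    return series


def five_tap_velocity_filter(series: AngularGazeSeries,
                             kernel=DEFAULT_KERNEL) -> AngularGazeSeries:
    """Smooth the speed series with a symmetric 5-tap FIR kernel.

    Edges (and samples adjacent to NaN gaps) are handled by window
    truncation with renormalization, so output length equals input length
    and the output never exceeds the raw maximum (the kernel is a convex
    combination).  NaN entries stay NaN.
    """
    if series.speed is None:
        raise ValueError("compute angular_velocity before filtering")
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or len(kernel) != 5 or np.any(kernel < 0) or kernel.sum() <= 0:
        raise ValueError("kernel must be 5 nonnegative taps with positive sum")
    kernel = kernel / kernel.sum()

    x = series.speed
    finite = np.isfinite(x)
    xz = np.where(finite, x, 0.0)
    num = np.convolve(xz, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    out = np.full_like(x, np.nan)
    ok = finite & (den > 0)
    out[ok] = num[ok] / den[ok]
    series.speed = out
    return series


def preprocess(rec: RawRecording, geom: ScreenGeometry | None = None,
               confidence_threshold: float = 0.5, kernel=DEFAULT_KERNEL,
               mask_blinks: bool = True) -> AngularGazeSeries:
    """Full preprocessing chain: angle conversion, velocity, 5-tap smoothing."""
    series = to_visual_angle(rec, geom, confidence_threshold, mask_blinks)
    angular_velocity(series)
    return five_tap_velocity_filter(series, kernel)
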