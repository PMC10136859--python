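"""Extraction of the 28 eye/gaze features from events and the pupil series.

Feature families: fixation (frequency; duration median, CV, skewness,
kurtosis), saccade (frequency; duration, amplitude with median + CV + skew
+ kurt; velocity and peak velocity with mean + CV + skew + kurt), blink
(frequency; duration mean), pupil (diameter mean, CV, skew, kurt).

Conventions: CV uses the n-1 standard-deviation denominator; skewness is
the Fisher-Pearson coefficient; kurtosis is excess (Fisher) by default with
a switch for raw.  Features whose underlying event sample is missing or too
small are encoded as NaN (never silently zero) and logged.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .events import OculomotorEvents
from .recordings import RawRecording
from .reference import FEATURE_NAMES, N_FEATURES

log = logging.getLogger(__name__)


def summary_stats(x, central: str = "median", excess_kurtosis: bool = True):
    """(central, cv, skewness, kurtosis) of a sample.

    ``central`` selects the central statistic ("median" or "mean") per the
    feature family.  Returns NaN for cv/skew/kurt when fewer than 2 values,
    and NaN for cv when the mean is 0.  Zero-dispersion samples get
    skewness 0 (documented policy) and the degenerate kurtosis of a
    constant (-3 excess / 0 raw).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (math.nan,) * 4
    if central == "median":
        c = float(np.median(x))
    elif central == "mean":
        c = float(np.mean(x))
    else:
        raise ValueError(f"central must be 'median' or 'mean', got {central!r}")
    if x.size < 2:
        return c, math.nan, math.nan, math.nan
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = sd / m if m != 0 else math.nan
    if sd == 0:
        log.warning("zero-dispersion sample: skewness reported as 0 by policy")
        return c, (0.0 if m != 0 else math.nan), 0.0, (-3.0 if excess_kurtosis else 0.0)
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=excess_kurtosis, bias=True))
    return c, cv, skew, kurt


def extract_features(events: OculomotorEvents, rec: RawRecording,
                     confidence_threshold: float = 0.5,
                     excess_kurtosis: bool = True) -> dict[str, float]:
    """Compute the 28-feature vector for one recording.

    Frequencies are event counts divided by the full recording duration.
    Pupil statistics are computed over samples outside blink intervals with
    confidence at or above the threshold.  Families with no events yield
    NaN entries.
    """
    duration = rec.duration_s
    if duration <= 0:
        raise ValueError("recording duration must be positive")
    out: dict[str, float] = {}

    fix_dur = [f.duration_ms for f in events.fixations]
    out["fix_freq"] = len(fix_dur) / duration
    (out["fix_duration_median"], out["fix_duration_cv"],
     out["fix_duration_skew"], out["fix_duration_kurt"]) = summary_stats(
        fix_dur, "median", excess_kurtosis)

    sac = events.saccades
    out["sac_freq"] = len(sac) / duration
    (out["sac_duration_median"], out["sac_duration_cv"],
     out["sac_duration_skew"], out["sac_duration_kurt"]) = summary_stats(
        [s.duration_ms for s in sac], "median", excess_kurtosis)
    (out["sac_amplitude_median"], out["sac_amplitude_cv"],
     out["sac_amplitude_skew"], out["sac_amplitude_kurt"]) = summary_stats(
        [s.amplitude_deg for s in sac], "median", excess_kurtosis)
    (out["sac_velocity_mean"], out["sac_velocity_cv"],
     out["sac_velocity_skew"], out["sac_velocity_kurt"]) = summary_stats(
        [s.mean_velocity_deg_s for s in sac], "mean", excess_kurtosis)
    (out["sac_peak_velocity_mean"], out["sac_peak_velocity_cv"],
     out["sac_peak_velocity_skew"], out["sac_peak_velocity_kurt"]) = summary_stats(
        [s.peak_velocity_deg_s for s in sac], "mean", excess_kurtosis)

    blinks = events.blinks
    out["blink_freq"] = len(blinks) / duration
    out["blink_duration_mean"] = (float(np.mean([b.duration_ms for b in blinks]))
                                  if blinks else math.nan)

    mask = np.isfinite(rec.pupil_mm) & (rec.confidence >= confidence_threshold)
    for s, e in rec.blinks:
        mask &= ~((rec.t >= s) & (rec.t <= e))
    (out["pupil_diameter_mean"], out["pupil_diameter_cv"],
     out["pupil_diameter_skew"], out["pupil_diameter_kurt"]) = summary_stats(
        rec.pupil_mm[mask], "mean", excess_kurtosis)

    missing = [k for k, v in out.items() if not np.isfinite(v)]
    if missing:
        log.info("%s/%s: %d feature(s) not available: %s",
                 rec.participant_id, rec.video_id, len(missing), missing)
    assert len(out) == N_FEATURES and tuple(out) == FEATURE_NAMES
    return out


class GazeFeatureExtractor(BaseEstimator):
    """Stateless transformer mapping (events, recording) pairs to feature rows."""

    def __init__(self, confidence_threshold: float = 0.5, excess_kurtosis: bool = True):
        self.confidence_threshold = confidence_threshold
        self.excess_kurtosis = excess_kurtosis

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of (OculomotorEvents, RawRecording) pairs."""
        rows, index = [], []
        for events, rec in X:
            rows.append(extract_features(events, rec, self.confidence_threshold,
                                         self.excess_kurtosis))
            index.append((rec.participant_id, rec.video_id))
        return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
            index, names=["participant_id", "video_id"]))
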