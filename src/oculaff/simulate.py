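"""Synthetic eye-tracking recordings with known ground truth.

The generator emulates 240 Hz recordings of a viewer watching a clip: an
alternating fixation/saccade process with lognormal fixation durations and
saccade amplitudes, saccades traced along great circles with a smooth
velocity profile whose peak follows a main-sequence relation, blinks as
confidence dropouts with missing pupil samples, and a pupil series with a
slow Ornstein-Uhlenbeck drift around a class baseline.  Class profiles are
parameterized from the published per-class feature means of the eSEE-d
study, so features extracted by the full pipeline recover the profile
targets in Monte-Carlo mean.

Construction guarantees (so that I-VT detection recovers the schedule):

* fixation jitter keeps angular speed far below the 45 deg/s threshold;
* saccade interior speeds have a floor (140 deg/s) and a bounded onset, so
  the 5-tap-smoothed speed crosses the threshold exactly one sample outside
  the motion on each side — a deterministic one-sample smear absorbed by
  scheduling each fixation two samples longer than its drawn duration;
* drawn fixation durations are floored just above the 55 ms minimum, so no
  fixation is discarded by detection and the lognormal *median* — the
  published, targeted statistic — is untouched by the flooring;
* blinks are scheduled between a fixation and the following saccade (gaze
  is held at the fixation centroid) so that blink masking never splits a
  fixation;
* blink count is drawn Poisson(rate x duration) up front and every blink is
  realized, making the blink-frequency estimator unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import Blink, Fixation, Saccade
from .recordings import RawRecording, ScreenGeometry
from .reference import (CLASS_FEATURE_MEANS, EMOTION_QUADRANT, QUADRANT_AROUSAL,
                        QUADRANT_VALENCE, RATING_MEANS, VIDEO_SET)


@dataclass(frozen=True)
class ClassProfile:
    """Generator parameters for one affect class.

    Duration/amplitude targets refer to the statistics the pipeline
    extracts (medians of lognormal draws, means of event processes).
    """

    label: str
    fix_duration_median_ms: float
    fix_duration_cv: float
    sac_amplitude_median_deg: float
    sac_amplitude_cv: float
    blink_rate_hz: float
    blink_duration_mean_ms: float
    pupil_mean_mm: float
    pupil_cv: float
    # main sequence: peak = asymptote * (1 - exp(-amplitude / scale))
    main_sequence_asymptote_deg_s: float = 450.0
    main_sequence_scale_deg: float = 10.0
    sac_velocity_floor_deg_s: float = 140.0
    blink_duration_cv: float = 0.25
    pupil_between_recording_sd_mm: float = 0.08
    pupil_drift_tau_s: float = 4.0
    pupil_drift_frac: float = 0.95  # share of pupil SD carried by the slow drift
    pupil_noise_sd_mm: float = 0.02
    jitter_step_deg: float = 0.012

    def peak_velocity(self, amplitude_deg: float) -> float:
        return self.main_sequence_asymptote_deg_s * (
            1.0 - math.exp(-amplitude_deg / self.main_sequence_scale_deg))


def class_profile(label: str) -> ClassProfile:
    """Packaged profile for an arousal/valence level or a quadrant.

    Level profiles (LA/MA/HA, NV/MV/PV) take their targets straight from
    the published class means.  Quadrant profiles (HANV/LANV/LAPV/MAMV)
    average the parent arousal-level and valence-level targets.
    """
    if label in CLASS_FEATURE_MEANS:
        m = CLASS_FEATURE_MEANS[label]
    elif label in QUADRANT_AROUSAL:
        a = CLASS_FEATURE_MEANS[QUADRANT_AROUSAL[label]]
        v = CLASS_FEATURE_MEANS[QUADRANT_VALENCE[label]]
        m = {k: (a[k] + v[k]) / 2 for k in a}
    else:
        raise KeyError(f"unknown class label {label!r}")
    # asymptote chosen so the peak at the median amplitude matches the
    # published mean peak velocity
    amp = m["sac_amplitude_median"]
    scale = 10.0
    asymptote = m["sac_peak_velocity_mean"] / (1.0 - math.exp(-amp / scale))
    return ClassProfile(
        label=label,
        fix_duration_median_ms=m["fix_duration_median"],
        fix_duration_cv=m["fix_duration_cv"],
        sac_amplitude_median_deg=amp,
        sac_amplitude_cv=m["sac_amplitude_cv"],
        blink_rate_hz=m["blink_freq"],
        blink_duration_mean_ms=m["blink_duration_mean"],
        pupil_mean_mm=m["pupil_diameter_mean"],
        pupil_cv=m["pupil_diameter_cv"],
        main_sequence_asymptote_deg_s=asymptote,
        main_sequence_scale_deg=scale,
    )


@dataclass
class GroundTruth:
    """Exact event schedule realized in a synthetic recording."""

    label: str
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)
    profile: ClassProfile | None = None


# ---------------------------------------------------------------------------
# geometry helpers: gaze directions as unit vectors, screen-plane projection
# ---------------------------------------------------------------------------


def _screen_to_direction(theta_x_deg, theta_y_deg):
    v = np.array([math.tan(math.radians(theta_x_deg)),
                  math.tan(math.radians(theta_y_deg)), 1.0])
    return v / np.linalg.norm(v)


def _direction_to_norm(v: np.ndarray, geom: ScreenGeometry):
    """Unit direction -> normalized screen coordinate."""
    x_mm = geom.distance_mm * v[..., 0] / v[..., 2]
    y_mm = geom.distance_mm * v[..., 1] / v[..., 2]
    return 0.5 + x_mm / geom.width_mm, 0.5 + y_mm / geom.height_mm


def _direction_theta(v: np.ndarray):
    tx = math.degrees(math.atan2(v[0], v[2]))
    ty = math.degrees(math.atan2(v[1], v[2]))
    return tx, ty


def _tangent_basis(u: np.ndarray):
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _rotate(u: np.ndarray, tangent: np.ndarray, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return math.cos(a) * u + math.sin(a) * tangent


def _slerp(u1: np.ndarray, u2: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    omega = math.acos(float(np.clip(np.dot(u1, u2), -1.0, 1.0)))
    if omega < 1e-12:
        return np.tile(u1, (len(fractions), 1))
    s = np.sin((1.0 - fractions) * omega)[:, None] * u1 + \
        np.sin(fractions * omega)[:, None] * u2
    return s / np.linalg.norm(s, axis=1, keepdims=True)


def _pick_landing(u: np.ndarray, amplitude_deg: float, geom: ScreenGeometry,
                  rng, margin_deg: float = 1.2) -> np.ndarray:
    """Land a saccade of the given great-angle amplitude on screen."""
    hx, hy = geom.half_extent_deg
    e1, e2 = _tangent_basis(u)
    phis = rng.uniform(0, 2 * math.pi) + np.linspace(0, 2 * math.pi, 32, endpoint=False)
    best, best_pen = None, math.inf
    candidates = []
    for phi in phis:
        tangent = math.cos(phi) * e1 + math.sin(phi) * e2
        v = _rotate(u, tangent, amplitude_deg)
        tx, ty = _direction_theta(v)
        pen = max(0.0, abs(tx) - (hx - margin_deg)) + max(0.0, abs(ty) - (hy - margin_deg))
        if pen == 0.0:
            candidates.append(v)
        elif pen < best_pen:
            best, best_pen = v, pen
    if candidates:
        return candidates[rng.integers(len(candidates))]
    return best  # extreme amplitudes: least off-screen landing


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------

_FIX, _SAC, _BLINK, _HOLD = "fix", "sac", "blink", "hold"


def _plan_segments(profile: ClassProfile, n: int, fs: float, rng) -> list[dict]:
    """Plan the segment tiling (kind, sample count, per-segment params).

    Fixation segments are scheduled two samples longer than the drawn
    duration to absorb the deterministic one-sample smoothing smear at each
    saccade boundary.  The plan is trimmed/extended to exactly ``n``
    samples, always ending in a fixation.
    """
    mu_f = math.log(profile.fix_duration_median_ms / 1000.0)
    sg_f = math.sqrt(math.log(1.0 + profile.fix_duration_cv ** 2))
    mu_a = math.log(profile.sac_amplitude_median_deg)
    sg_a = math.sqrt(math.log(1.0 + profile.sac_amplitude_cv ** 2))
    k_floor = int(round(0.055 * fs)) + 5  # detected duration stays above 55 ms

    # blink budget drawn up front so the realized count is Poisson(rate*T)
    n_blinks = int(rng.poisson(profile.blink_rate_hz * (n - 1) / fs))
    cv_b = profile.blink_duration_cv
    mu_b = math.log(profile.blink_duration_mean_ms / 1000.0) - 0.5 * math.log(1 + cv_b ** 2)
    sg_b = math.sqrt(math.log(1 + cv_b ** 2))
    blink_ks = [max(4, int(round(float(rng.lognormal(mu_b, sg_b)) * fs)) + 1)
                for _ in range(n_blinks)]

    target_nb = max(2 * k_floor, n - sum(blink_ks))
    segs: list[dict] = []
    nb = 0
    while True:
        d = float(rng.lognormal(mu_f, sg_f))
        k_f = max(k_floor, int(round(d * fs)) + 3)
        segs.append({"kind": _FIX, "k": k_f})
        nb += k_f
        if nb >= target_nb:
            break
        amp = float(rng.lognormal(mu_a, sg_a))
        peak = profile.peak_velocity(amp)
        floor = profile.sac_velocity_floor_deg_s
        m = int(round(fs * 2.0 * amp / (peak + floor)))
        m = min(max(m, 6), int(round(0.25 * fs)))
        segs.append({"kind": _SAC, "k": m - 1, "amp": amp, "peak": peak, "m": m})
        nb += m - 1

    # insert blinks after randomly chosen fixations (not the last two); two
    # valid "hold" samples at the centroid follow each blink so the next
    # saccade's onset is fully observable after blink masking
    fix_positions = [i for i, s in enumerate(segs) if s["kind"] == _FIX][:-2]
    n_ins = min(n_blinks, len(fix_positions))
    for pos, k_b in zip(sorted(rng.choice(len(fix_positions), size=n_ins, replace=False),
                               reverse=True) if n_ins else [], blink_ks):
        segs.insert(fix_positions[pos] + 1, {"kind": _HOLD, "k": 2})
        segs.insert(fix_positions[pos] + 1, {"kind": _BLINK, "k": k_b})

    # trim / extend to exactly n samples, ending in a fixation
    total = sum(s["k"] for s in segs)
    while total > n:
        last = segs[-1]
        excess = total - n
        if last["kind"] == _FIX and last["k"] - excess >= k_floor:
            last["k"] -= excess
            total = n
        else:
            total -= last["k"]
            segs.pop()
    while segs and segs[-1]["kind"] != _FIX:
        total -= segs[-1]["k"]
        segs.pop()
    if not segs:
        segs = [{"kind": _FIX, "k": n}]
        total = n
    if total < n:
        segs[-1]["k"] += n - total
    return segs


def generate_recording(profile: ClassProfile, duration_s: float = 60.0,
                       fs_hz: float = 240.0, seed=None,
                       geom: ScreenGeometry | None = None,
                       noiseless: bool = False,
                       participant_id: str = "sim", video_id: str = "sim",
                       ) -> tuple[RawRecording, GroundTruth]:
    """Generate one synthetic recording and its exact ground truth.

    ``noiseless`` switches off fixation jitter, pupil noise/drift and
    between-recording variability, leaving only the event process — useful
    for exact event-boundary recovery checks.  Reproducible given ``seed``
    (an ``int`` or a ``numpy.random.Generator``).
    """
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration_s and fs_hz must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = geom or ScreenGeometry()
    n = int(round(duration_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz

    segs = _plan_segments(profile, n, fs_hz, rng)

    hx, hy = geom.half_extent_deg
    u = _screen_to_direction(float(rng.uniform(-0.3 * hx, 0.3 * hx)),
                             float(rng.uniform(-0.3 * hy, 0.3 * hy)))
    dirs = np.empty((n, 3))
    blink_mask = np.zeros(n, dtype=bool)
    gt = GroundTruth(label=profile.label, profile=profile)
    blink_intervals: list[tuple[float, float]] = []

    i = 0
    for seg in segs:
        k = seg["k"]
        sl = slice(i, i + k)
        if seg["kind"] == _FIX:
            e1, e2 = _tangent_basis(u)
            if noiseless or profile.jitter_step_deg == 0:
                dirs[sl] = u
            else:
                # bounded OU jitter in the tangent plane (miniature motion)
                steps = rng.normal(0.0, profile.jitter_step_deg, size=(k, 2))
                off = np.empty((k, 2))
                acc = np.zeros(2)
                for j in range(k):
                    acc = 0.9 * acc + steps[j]
                    acc = np.clip(acc, -0.15, 0.15)
                    off[j] = acc
                mag = np.linalg.norm(off, axis=1)
                mag_safe = np.where(mag > 0, mag, 1.0)
                tang = (off[:, 0, None] * e1 + off[:, 1, None] * e2) / mag_safe[:, None]
                dirs[sl] = (np.cos(np.radians(mag))[:, None] * u
                            + np.sin(np.radians(mag))[:, None] * tang)
            tx, ty = _direction_theta(u)
            gt.fixations.append(Fixation(
                start_s=t[i], end_s=t[i + k - 1], duration_ms=(k - 1) / fs_hz * 1000.0,
                centroid_x_deg=tx, centroid_y_deg=ty))
        elif seg["kind"] == _SAC:
            m = seg["m"]
            u2 = _pick_landing(u, seg["amp"], geom, rng)
            floor = profile.sac_velocity_floor_deg_s
            v = floor + (seg["peak"] - floor) * np.sin(
                math.pi * (np.arange(1, m + 1) - 0.5) / m) ** 2
            frac = np.cumsum(v) / v.sum()
            dirs[sl] = _slerp(u, u2, frac[:k])
            gt.saccades.append(Saccade(
                start_s=t[i - 1], end_s=t[i + k], duration_ms=(k + 1) / fs_hz * 1000.0,
                amplitude_deg=seg["amp"],
                mean_velocity_deg_s=float(v.mean()), peak_velocity_deg_s=float(v.max())))
            u = u2
        elif seg["kind"] == _BLINK:  # gaze held at the current centroid, tracking lost
            dirs[sl] = u
            blink_mask[sl] = True
            blink_intervals.append((t[i], t[i + k - 1]))
            gt.blinks.append(Blink(start_s=t[i], end_s=t[i + k - 1],
                                   duration_ms=(k - 1) / fs_hz * 1000.0))
        else:  # hold: valid samples at the centroid bridging blink -> saccade
            dirs[sl] = u
        i += k
    assert i == n

    gx, gy = _direction_to_norm(dirs, geom)

    # pupil: class baseline + slow OU drift + measurement noise, lost in blinks
    if noiseless:
        pupil = np.full(n, profile.pupil_mean_mm)
    else:
        baseline = profile.pupil_mean_mm + float(
            rng.normal(0.0, profile.pupil_between_recording_sd_mm))
        total_sd = profile.pupil_cv * profile.pupil_mean_mm
        drift_sd = profile.pupil_drift_frac * total_sd
        noise_sd = math.sqrt(max(total_sd ** 2 - drift_sd ** 2,
                                 profile.pupil_noise_sd_mm ** 2))
        rho = math.exp(-1.0 / (fs_hz * profile.pupil_drift_tau_s))
        innov = rng.normal(0.0, drift_sd * math.sqrt(1 - rho ** 2), size=n)
        drift = np.empty(n)
        drift[0] = rng.normal(0.0, drift_sd)
        for j in range(1, n):
            drift[j] = rho * drift[j - 1] + innov[j]
        pupil = baseline + drift + rng.normal(0.0, noise_sd, size=n)
    pupil = np.where(blink_mask, np.nan, pupil)

    confidence = np.ones(n) if noiseless else np.clip(
        1.0 - np.abs(rng.normal(0.0, 0.01, size=n)), 0.55, 1.0)
    confidence[blink_mask] = 0.02

    rec = RawRecording(
        participant_id=participant_id, video_id=video_id, fs_hz=fs_hz,
        t=t, gaze_x=gx, gaze_y=gy, pupil_mm=pupil, confidence=confidence,
        blinks=blink_intervals, aborted=False, clip_duration_s=duration_s)
    return rec, gt


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSession:
    manifest: pd.DataFrame
    ratings: pd.DataFrame
    recordings: list[RawRecording]
    ground_truths: list[GroundTruth]


def _offset_profile(profile: ClassProfile, mult: dict[str, float]) -> ClassProfile:
    return replace(
        profile,
        pupil_mean_mm=profile.pupil_mean_mm * mult["pupil"],
        fix_duration_median_ms=profile.fix_duration_median_ms * mult["fix"],
        sac_amplitude_median_deg=profile.sac_amplitude_median_deg * mult["amp"],
        blink_rate_hz=profile.blink_rate_hz * mult["blink"],
    )


def generate_session(n_participants: int, seed=None, duration_s: float | None = None,
                     fs_hz: float = 240.0, rating_noise_sd: float = 1.0,
                     participant_cv: float = 0.05,
                     profiles: dict[str, ClassProfile] | None = None) -> SyntheticSession:
    """Generate a full multi-participant session.

    Each participant watches the 10-clip stimulus set (2 clips per emotion
    including neutral); each recording is generated from the quadrant
    profile of the clip's emotion, with participant-level multiplicative
    offsets (lognormal, mean 1, coefficient ``participant_cv``) on pupil
    baseline, fixation duration, saccade amplitude and blink rate, so the
    random-intercept structure the screening model assumes is present.
    DES ratings are drawn around the published per-emotion mean vectors
    with truncated-normal noise ``rating_noise_sd`` (0 reproduces the mean
    vectors, hence each class's own label).

    ``duration_s`` overrides every clip duration (useful for fast tests).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profiles = profiles or {q: class_profile(q) for q in
                            ("HANV", "LANV", "LAPV", "MAMV")}
    sigma = math.sqrt(math.log(1 + participant_cv ** 2))

    man_rows, rat_rows, recordings, gts = [], [], [], []
    for p in range(n_participants):
        pid = f"p{p + 1:02d}"
        mult = {k: float(rng.lognormal(-0.5 * sigma ** 2, sigma)) if participant_cv > 0
                else 1.0 for k in ("pupil", "fix", "amp", "blink")}
        for video_id, emotion, vid_dur in VIDEO_SET:
            dur = float(duration_s or vid_dur)
            quadrant = EMOTION_QUADRANT[emotion]
            prof = _offset_profile(profiles[quadrant], mult)
            rec, gt = generate_recording(prof, duration_s=dur, fs_hz=fs_hz,
                                         seed=rng, participant_id=pid,
                                         video_id=video_id)
            recordings.append(rec)
            gts.append(gt)
            man_rows.append({"participant_id": pid, "video_id": video_id,
                             "emotion": emotion, "duration_s": dur})
            scores = {}
            for emo, mean in RATING_MEANS[emotion].items():
                val = mean + (float(rng.normal(0, rating_noise_sd))
                              if rating_noise_sd > 0 else 0.0)
                scores[emo] = float(np.clip(val, 0.0, 10.0))
            rat_rows.append({"participant_id": pid, "video_id": video_id, **scores})
    return SyntheticSession(manifest=pd.DataFrame(man_rows),
                            ratings=pd.DataFrame(rat_rows),
                            recordings=recordings, ground_truths=gts)


def luminance_probe(rec: RawRecording, coupling: float, frame_rate_hz: float = 25.0,
                    seed=None) -> np.ndarray:
    """Synthetic per-frame V (brightness) series with a chosen pupil coupling.

    Emits a frame-rate series whose correlation with the recording's
    frame-averaged pupil diameter is approximately ``coupling`` — a probe
    for the luminance confound check, not a model of real video luminance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(math.floor(rec.duration_s * frame_rate_hz)) + 1
    frame_idx = np.floor((rec.t - rec.t[0]) * frame_rate_hz).astype(int)
    ok = np.isfinite(rec.pupil_mm) & (frame_idx < n_frames)
    sums = np.bincount(frame_idx[ok], weights=rec.pupil_mm[ok], minlength=n_frames)
    counts = np.bincount(frame_idx[ok], minlength=n_frames)
    p = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    z = (p - np.nanmean(p)) / (np.nanstd(p) if np.nanstd(p) > 0 else 1.0)
    z = np.nan_to_num(z)
    noise = rng.normal(0.0, 1.0, size=n_frames)
    v = coupling * z + math.sqrt(max(0.0, 1.0 - coupling ** 2)) * noise
    return 0.5 + 0.1 * v  # arbitrary brightness units
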