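"""Reference values published with the eSEE-d eye-tracking study.

The eSEE-d dataset (Zenodo accession 10.5281/zenodo.5775674) ships with a
set of published summary statistics that this package uses in two ways:

* as *targets* for the synthetic recording generator, so that every stage of
  the pipeline can be exercised and validated without downloading the real
  recordings (see :mod:`oculaff.simulate`);
* as *fixtures* for downstream stages whose inputs would normally be the
  screening results computed on the real data (feature rankings, predictor
  sets, network presets).

All tables here are per arousal class (LA/MA/HA: low/medium/high emotional
arousal), per valence class (NV/MV/PV: negative/medium/positive emotional
valence), or per quadrant of the arousal-valence plane (HANV, LANV, LAPV,
MAMV).
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Feature schema: the 28 eye/gaze features, grouped by event family.
# Fixation duration, saccade amplitude and saccade duration are medians;
# saccade velocity, peak saccade velocity, blink duration and pupil diameter
# are means.  "cv" is the coefficient of variation (sd / mean).
# --------------------------------------------------------------------------
FEATURE_NAMES: tuple[str, ...] = (
    "fix_freq",
    "fix_duration_median",
    "fix_duration_cv",
    "fix_duration_skew",
    "fix_duration_kurt",
    "sac_freq",
    "sac_duration_median",
    "sac_duration_cv",
    "sac_duration_skew",
    "sac_duration_kurt",
    "sac_amplitude_median",
    "sac_amplitude_cv",
    "sac_amplitude_skew",
    "sac_amplitude_kurt",
    "sac_velocity_mean",
    "sac_velocity_cv",
    "sac_velocity_skew",
    "sac_velocity_kurt",
    "sac_peak_velocity_mean",
    "sac_peak_velocity_cv",
    "sac_peak_velocity_skew",
    "sac_peak_velocity_kurt",
    "blink_freq",
    "blink_duration_mean",
    "pupil_diameter_mean",
    "pupil_diameter_cv",
    "pupil_diameter_skew",
    "pupil_diameter_kurt",
)

N_FEATURES = 28

AROUSAL_CLASSES = ("LA", "MA", "HA")
VALENCE_CLASSES = ("NV", "MV", "PV")
QUADRANTS = ("HANV", "LANV", "LAPV", "MAMV")

# Emotion -> quadrant of the arousal-valence circumplex.
EMOTION_QUADRANT = {
    "anger": "HANV",
    "disgust": "HANV",
    "sadness": "LANV",
    "tenderness": "LAPV",
    "neutral": "MAMV",
}
QUADRANT_AROUSAL = {"HANV": "HA", "LANV": "LA", "LAPV": "LA", "MAMV": "MA"}
QUADRANT_VALENCE = {"HANV": "NV", "LANV": "NV", "LAPV": "PV", "MAMV": "MV"}

# --------------------------------------------------------------------------
# Published mixed-model estimated feature means per arousal/valence class
# (units as in the schema: ms for durations, deg for amplitude, deg/s for
# velocities, events/s for frequencies, mm for pupil diameter).
# Column order: LA, MA, HA, NV, MV, PV.
# --------------------------------------------------------------------------
_CLASS_COLUMNS = AROUSAL_CLASSES + VALENCE_CLASSES

_CLASS_MEAN_ROWS = {
    "fix_freq": (2.10, 2.09, 2.20, 2.17, 2.09, 2.09),
    "fix_duration_median": (314.50, 306.94, 295.52, 303.62, 307.48, 310.83),
    "fix_duration_cv": (0.87, 0.89, 0.87, 0.87, 0.89, 0.89),
    "fix_duration_skew": (2.51, 2.38, 2.64, 2.58, 2.38, 2.56),
    "fix_duration_kurt": (9.48, 7.92, 10.92, 10.35, 7.91, 9.59),
    "sac_freq": (2.48, 2.70, 3.05, 2.83, 2.68, 2.54),
    "sac_amplitude_median": (14.01, 13.88, 14.00, 14.08, 13.89, 13.77),
    "sac_amplitude_cv": (0.18, 0.20, 0.18, 0.18, 0.20, 0.18),
    "sac_amplitude_skew": (0.23, 0.37, 0.34, 0.24, 0.36, 0.42),
    "sac_amplitude_kurt": (7.44, 6.59, 7.85, 7.60, 6.58, 7.76),
    "sac_velocity_mean": (223.90, 240.77, 234.27, 231.71, 240.63, 220.16),
    "sac_velocity_cv": (0.78, 0.74, 0.74, 0.76, 0.74, 0.76),
    "sac_velocity_skew": (1.35, 1.08, 1.20, 1.22, 1.08, 1.47),
    "sac_velocity_kurt": (2.43, 1.41, 2.21, 2.05, 1.40, 3.18),
    "sac_peak_velocity_mean": (299.83, 320.39, 310.35, 308.00, 320.27, 295.27),
    "sac_peak_velocity_cv": (0.75, 0.72, 0.71, 0.73, 0.72, 0.74),
    "sac_peak_velocity_skew": (1.00, 0.78, 0.87, 0.89, 0.78, 1.08),
    "sac_peak_velocity_kurt": (1.10, 0.59, 1.03, 0.92, 0.58, 1.54),
    "sac_duration_median": (22.03, 23.63, 22.63, 22.46, 23.63, 21.87),
    "sac_duration_cv": (0.99, 0.96, 1.04, 1.02, 0.96, 0.97),
    "sac_duration_skew": (2.73, 2.60, 2.96, 2.87, 2.60, 2.74),
    "sac_duration_kurt": (9.87, 9.55, 12.21, 11.29, 9.51, 10.05),
    "blink_freq": (0.21, 0.27, 0.22, 0.23, 0.27, 0.19),
    "blink_duration_mean": (215.32, 214.88, 220.45, 218.83, 214.79, 214.61),
    "pupil_diameter_mean": (3.85, 3.74, 3.95, 3.87, 3.74, 4.00),
    "pupil_diameter_cv": (0.067, 0.076, 0.076, 0.073, 0.076, 0.067),
    "pupil_diameter_skew": (-0.29, -0.28, -0.29, -0.23, -0.27, -0.47),
    "pupil_diameter_kurt": (2.34, 1.71, 1.86, 1.80, 1.71, 3.09),
}

#: ``CLASS_FEATURE_MEANS[cls][feature]`` -> published class mean.
CLASS_FEATURE_MEANS: dict[str, dict[str, float]] = {
    cls: {feat: row[i] for feat, row in _CLASS_MEAN_ROWS.items()}
    for i, cls in enumerate(_CLASS_COLUMNS)
}

# --------------------------------------------------------------------------
# Published DES (differential emotions scale) mean rating vectors, one row
# per subjective annotation, columns (anger, disgust, sadness, tenderness)
# on the 0-10 scale.  The neutral row is not published (neutral is defined
# by all scores < 4); the value used by the generator is a low flat vector.
# --------------------------------------------------------------------------
RATING_MEANS: dict[str, dict[str, float]] = {
    "anger": {"anger": 7.7, "disgust": 4.5, "sadness": 5.7, "tenderness": 0.2},
    "disgust": {"anger": 4.2, "disgust": 8.4, "sadness": 4.0, "tenderness": 0.1},
    "sadness": {"anger": 3.8, "disgust": 3.3, "sadness": 7.5, "tenderness": 0.1},
    "tenderness": {"anger": 0.4, "disgust": 0.1, "sadness": 0.1, "tenderness": 6.4},
    "neutral": {"anger": 1.0, "disgust": 1.0, "sadness": 1.0, "tenderness": 1.0},
}

# --------------------------------------------------------------------------
# Published screening outcomes (omnibus mixed-model p-value per feature and
# Bonferroni-adjusted pairwise p-values).  Only features with a significant
# omnibus effect are listed; everything else did not pass screening.
# --------------------------------------------------------------------------
AROUSAL_SCREENING: dict[str, dict] = {
    "fix_freq": {"p": 0.009, "pairs": {("LA", "MA"): 1.000, ("LA", "HA"): 0.030, ("MA", "HA"): 0.027}},
    "fix_duration_median": {"p": 0.005, "pairs": {("LA", "MA"): 0.744, ("LA", "HA"): 0.003, ("MA", "HA"): 0.230}},
    "fix_duration_skew": {"p": 0.043, "pairs": {("LA", "MA"): 0.700, ("LA", "HA"): 0.478, ("MA", "HA"): 0.038}},
    "fix_duration_kurt": {"p": 0.007, "pairs": {("LA", "MA"): 0.290, ("LA", "HA"): 0.328, ("MA", "HA"): 0.005}},
    "sac_freq": {"p": 0.001, "pairs": {("LA", "MA"): 0.604, ("LA", "HA"): 0.000, ("MA", "HA"): 0.095}},
    "sac_amplitude_cv": {"p": 0.043, "pairs": {("LA", "MA"): 0.048, ("LA", "HA"): 1.000, ("MA", "HA"): 0.139}},
    "sac_velocity_cv": {"p": 0.014, "pairs": {("LA", "MA"): 0.065, ("LA", "HA"): 0.023, ("MA", "HA"): 1.000}},
    "sac_velocity_skew": {"p": 0.045, "pairs": {("LA", "MA"): 0.043, ("LA", "HA"): 0.367, ("MA", "HA"): 0.818}},
    "sac_peak_velocity_cv": {"p": 0.019, "pairs": {("LA", "MA"): 0.132, ("LA", "HA"): 0.023, ("MA", "HA"): 1.000}},
    "sac_duration_median": {"p": 0.000, "pairs": {("LA", "MA"): 0.000, ("LA", "HA"): 0.257, ("MA", "HA"): 0.029}},
    "sac_duration_cv": {"p": 0.004, "pairs": {("LA", "MA"): 0.597, ("LA", "HA"): 0.089, ("MA", "HA"): 0.004}},
    "sac_duration_skew": {"p": 0.005, "pairs": {("LA", "MA"): 0.830, ("LA", "HA"): 0.076, ("MA", "HA"): 0.005}},
    "sac_duration_kurt": {"p": 0.021, "pairs": {("LA", "MA"): 1.000, ("LA", "HA"): 0.060, ("MA", "HA"): 0.045}},
    "blink_freq": {"p": 0.001, "pairs": {("LA", "MA"): 0.001, ("LA", "HA"): 1.000, ("MA", "HA"): 0.004}},
    "pupil_diameter_mean": {"p": 0.000, "pairs": {("LA", "MA"): 0.08, ("LA", "HA"): 0.093, ("MA", "HA"): 0.000}},
    "pupil_diameter_cv": {"p": 0.008, "pairs": {("LA", "MA"): 0.042, ("LA", "HA"): 0.014, ("MA", "HA"): 1.000}},
}

VALENCE_SCREENING: dict[str, dict] = {
    "fix_freq": {"p": 0.045, "pairs": {("NV", "MV"): 0.120, ("NV", "PV"): 0.187, ("MV", "PV"): 1.000}},
    "fix_duration_kurt": {"p": 0.020, "pairs": {("NV", "MV"): 0.015, ("NV", "PV"): 1.000, ("MV", "PV"): 0.419}},
    "sac_amplitude_median": {"p": 0.000, "pairs": {("NV", "MV"): 0.047, ("NV", "PV"): 0.001, ("MV", "PV"): 0.701}},
    "sac_amplitude_cv": {"p": 0.047, "pairs": {("NV", "MV"): 0.063, ("NV", "PV"): 1.000, ("MV", "PV"): 0.128}},
    "sac_velocity_skew": {"p": 0.011, "pairs": {("NV", "MV"): 0.535, ("NV", "PV"): 0.065, ("MV", "PV"): 0.009}},
    "sac_peak_velocity_skew": {"p": 0.023, "pairs": {("NV", "MV"): 0.619, ("NV", "PV"): 0.116, ("MV", "PV"): 0.019}},
    "sac_duration_median": {"p": 0.000, "pairs": {("NV", "MV"): 0.004, ("NV", "PV"): 0.400, ("MV", "PV"): 0.001}},
    "sac_duration_cv": {"p": 0.003, "pairs": {("NV", "MV"): 0.007, ("NV", "PV"): 0.074, ("MV", "PV"): 1.000}},
    "sac_duration_skew": {"p": 0.031, "pairs": {("NV", "MV"): 0.029, ("NV", "PV"): 0.751, ("MV", "PV"): 0.950}},
    "blink_freq": {"p": 0.000, "pairs": {("NV", "MV"): 0.005, ("NV", "PV"): 0.068, ("MV", "PV"): 0.000}},
    "pupil_diameter_mean": {"p": 0.000, "pairs": {("NV", "MV"): 0.013, ("NV", "PV"): 0.018, ("MV", "PV"): 0.000}},
    "pupil_diameter_kurt": {"p": 0.010, "pairs": {("NV", "MV"): 1.000, ("NV", "PV"): 0.013, ("MV", "PV"): 0.021}},
}

# Pairwise columns: (LANV,MAMV), (LANV,LAPV), (LANV,HANV), (MAMV,LAPV),
# (MAMV,HANV), (LAPV,HANV).
_Q = (("LANV", "MAMV"), ("LANV", "LAPV"), ("LANV", "HANV"),
      ("MAMV", "LAPV"), ("MAMV", "HANV"), ("LAPV", "HANV"))


def _qrow(p, *pair_ps):
    return {"p": p, "pairs": dict(zip(_Q, pair_ps))}


QUADRANT_SCREENING: dict[str, dict] = {
    "fix_freq": _qrow(0.019, 1.000, 1.000, 0.483, 1.000, 0.046, 0.086),
    "fix_duration_median": _qrow(0.012, 1.000, 1.000, 0.014, 1.000, 0.353, 0.176),
    "fix_duration_kurt": _qrow(0.019, 0.819, 1.000, 1.000, 1.000, 0.010, 1.000),
    "sac_freq": _qrow(0.002, 1.000, 1.000, 0.003, 1.000, 0.182, 0.034),
    "sac_amplitude_median": _qrow(0.000, 0.005, 0.000, 0.078, 1.000, 1.000, 0.081),
    "sac_velocity_cv": _qrow(0.017, 0.052, 1.000, 0.022, 1.000, 1.000, 0.820),
    "sac_velocity_skew": _qrow(0.021, 0.918, 0.559, 1.000, 0.012, 1.000, 0.133),
    "sac_peak_velocity_cv": _qrow(0.019, 0.083, 1.000, 0.017, 1.000, 1.000, 0.907),
    "sac_peak_velocity_skew": _qrow(0.041, 0.849, 1.000, 1.000, 0.030, 1.000, 0.208),
    "sac_duration_median": _qrow(0.001, 0.008, 1.000, 1.000, 0.001, 0.059, 0.451),
    "sac_duration_cv": _qrow(0.004, 0.440, 1.000, 1.000, 1.000, 0.007, 0.068),
    "sac_duration_skew": _qrow(0.015, 1.000, 1.000, 0.279, 1.000, 0.012, 0.496),
    "blink_freq": _qrow(0.000, 0.299, 0.074, 1.000, 0.000, 0.007, 0.352),
    "pupil_diameter_mean": _qrow(0.000, 1.000, 0.000, 0.000, 0.000, 0.000, 1.000),
    "pupil_diameter_cv": _qrow(0.025, 0.212, 1.000, 0.102, 0.297, 1.000, 0.148),
    "pupil_diameter_skew": _qrow(0.037, 0.961, 0.022, 0.680, 0.470, 1.000, 0.540),
    "pupil_diameter_kurt": _qrow(0.020, 1.000, 0.043, 1.000, 0.036, 1.000, 0.064),
}

SCREENING_BY_TARGET = {
    "arousal": AROUSAL_SCREENING,
    "valence": VALENCE_SCREENING,
    "combined": QUADRANT_SCREENING,
}

# --------------------------------------------------------------------------
# Published predictor sets after correlation pruning (sizes 6 / 8 / 7).
# --------------------------------------------------------------------------
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "arousal": (
        "fix_freq",
        "blink_freq",
        "pupil_diameter_mean",
        "fix_duration_kurt",
        "sac_duration_cv",
        "pupil_diameter_cv",
    ),
    "valence": (
        "fix_freq",
        "blink_freq",
        "sac_amplitude_median",
        "sac_duration_median",
        "pupil_diameter_mean",
        "fix_duration_kurt",
        "sac_duration_cv",
        "pupil_diameter_kurt",
    ),
    "combined": (
        "sac_freq",
        "blink_freq",
        "sac_amplitude_median",
        "pupil_diameter_mean",
        "fix_duration_kurt",
        "sac_duration_cv",
        "pupil_diameter_kurt",
    ),
}

# --------------------------------------------------------------------------
# Published network presets: task -> hidden layer widths.  Task names use
# '+' for merged classes and '/' between classes.
# --------------------------------------------------------------------------
NETWORK_PRESETS: dict[str, tuple[int, ...]] = {
    # arousal tasks
    "LA+MA/HA": (128, 32),
    "HA/LA": (128, 64),
    "HA/MA": (128, 64),
    "MA/LA": (128, 64),
    "HA/MA/LA": (256, 64, 32),
    # valence tasks
    "NV+MV/PV": (64, 16),
    "PV/NV": (32, 8),
    "PV/MV": (32, 8),
    "MV/NV": (64, 32),
    "PV/MV/NV": (128, 64, 32),
    # joint quadrant task
    "MAMV/HANV/LANV/LAPV": (128, 64, 16),
}

# --------------------------------------------------------------------------
# The stimulus set: 10 emotion-evoking clips (2 per emotion incl. neutral),
# with durations in seconds.
# --------------------------------------------------------------------------
VIDEO_SET: tuple[tuple[str, str, float], ...] = (
    ("american_history_x", "anger", 77.0),
    ("benny_and_joon", "tenderness", 121.0),
    ("blue_2", "neutral", 40.0),
    ("ghost", "tenderness", 79.0),
    ("man_bites_dog_1", "disgust", 92.0),
    ("schindlers_list_1", "sadness", 58.0),
    ("schindlers_list_2", "anger", 115.0),
    ("dreamlife_of_angels", "sadness", 120.0),
    ("the_lover", "neutral", 43.0),
    ("trainspotting_2", "disgust", 60.0),
)
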