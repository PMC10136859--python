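"""Affect annotation from differential-emotion-scale (DES) self-reports.

Participants rate four emotions (anger, disgust, sadness, tenderness) on an
11-point 0-10 scale after each clip.  The subjective annotation rule: an
emotion is assigned iff its score is at least 4 *and* exceeds every other
emotion's score by at least 1 point; otherwise the response is neutral.
Each emotion maps to a fixed quadrant of the arousal-valence plane
(anger/disgust -> HANV, sadness -> LANV, tenderness -> LAPV, neutral ->
MAMV), which determines the arousal (LA/MA/HA) and valence (NV/MV/PV)
levels used by the classifiers.

Also provides the stimulus-validation statistics: per-emotion hit rate,
mean target rating, and pairwise discreteness t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import EMOTION_QUADRANT, QUADRANT_AROUSAL, QUADRANT_VALENCE

DES_EMOTIONS = ("anger", "disgust", "sadness", "tenderness")


@dataclass(frozen=True)
class DESRating:
    """One self-assessment: four emotion scores on the 0-10 scale.

    Scores are accepted as reals in [0, 10] (not just the 11 integer
    points) so that group mean-rating vectors can flow through the same
    annotation rule.
    """

    anger: float
    disgust: float
    sadness: float
    tenderness: float

    def __post_init__(self):
        for e in DES_EMOTIONS:
            v = getattr(self, e)
            if not 0 <= v <= 10:
                raise ValueError(f"{e} rating {v} outside [0, 10]")

    def scores(self) -> dict[str, float]:
        return {e: getattr(self, e) for e in DES_EMOTIONS}


@dataclass(frozen=True)
class AffectLabel:
    emotion: str
    arousal: str
    valence: str
    quadrant: str


def label_for_emotion(emotion: str) -> AffectLabel:
    """AffectLabel for an emotion via the fixed quadrant mapping."""
    quadrant = EMOTION_QUADRANT[emotion]
    return AffectLabel(emotion=emotion, arousal=QUADRANT_AROUSAL[quadrant],
                       valence=QUADRANT_VALENCE[quadrant], quadrant=quadrant)


def subjective_annotation(r: DESRating, min_score: float = 4.0,
                          min_margin: float = 1.0) -> AffectLabel:
    """Apply the subjective-annotation rule to one rating.

    The winning emotion must score at least ``min_score`` and beat every
    other emotion by at least ``min_margin`` ("at least 1 point" is read as
    >= 1.0); ties therefore fall through to neutral.
    """
    scores = r.scores()
    best = max(scores, key=scores.get)
    others = [v for e, v in scores.items() if e != best]
    if scores[best] >= min_score and all(scores[best] >= v + min_margin for v in others):
        return label_for_emotion(best)
    return label_for_emotion("neutral")


def annotate_table(ratings: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Join ratings with the manifest and annotate every recording.

    Returns one row per (participant_id, video_id) with the objective
    emotion and the subjective emotion/arousal/valence/quadrant labels.
    """
    df = ratings.merge(manifest, on=["participant_id", "video_id"], validate="one_to_one")
    labels = [subjective_annotation(DESRating(**{e: row[e] for e in DES_EMOTIONS}))
              for row in df.to_dict("records")]
    df["objective_emotion"] = df["emotion"]
    df["subjective_emotion"] = [lab.emotion for lab in labels]
    df["arousal"] = [lab.arousal for lab in labels]
    df["valence"] = [lab.valence for lab in labels]
    df["quadrant"] = [lab.quadrant for lab in labels]
    return df.drop(columns=["emotion"])


def hit_rate(labels: list[tuple[str, str]]) -> dict[str, float]:
    """Per-emotion fraction of videos whose subjective label hits the target.

    ``labels`` is a list of (objective, subjective) pairs.  Emotions with
    zero videos get NaN.
    """
    if not labels:
        raise ValueError("hit_rate needs a nonempty label list")
    out = {}
    objectives = [o for o, _ in labels]
    for emotion in dict.fromkeys(objectives):
        hits = [s == o for o, s in labels if o == emotion]
        out[emotion] = float(np.mean(hits))
    return out


def mean_target_rating(ratings: pd.DataFrame, manifest: pd.DataFrame) -> dict[str, float]:
    """Mean score of each target emotion over that emotion's own videos."""
    df = ratings.merge(manifest, on=["participant_id", "video_id"])
    out = {}
    for emotion in df["emotion"].unique():
        out[emotion] = (float(df.loc[df["emotion"] == emotion, emotion].mean())
                        if emotion in DES_EMOTIONS else math.nan)
    return out


def discreteness_test(ratings: pd.DataFrame, annotation_col: str = "subjective_emotion"
                      ) -> pd.DataFrame:
    """Pairwise paired t-tests of annotation-emotion score vs the others.

    For each subjective annotation group (excluding neutral), tests whether
    the annotated emotion's score exceeds each other emotion's score over
    the same recordings.  Returns rows (annotation, other, t, df, p).
    A zero-variance difference yields the exact-limit p (0 when the mean
    difference is nonzero, 1 when it is zero) with a warning.
    """
    rows = []
    for annotation, grp in ratings.groupby(annotation_col):
        if annotation not in DES_EMOTIONS or len(grp) < 2:
            continue
        for other in DES_EMOTIONS:
            if other == annotation:
                continue
            d = grp[annotation].to_numpy(float) - grp[other].to_numpy(float)
            if np.std(d, ddof=1) == 0:
                warnings.warn("zero-variance paired difference; p reported as exact limit")
                t = math.inf if d.mean() > 0 else (-math.inf if d.mean() < 0 else 0.0)
                p = 1.0 if d.mean() == 0 else 0.0
            else:
                t, p = stats.ttest_rel(grp[annotation], grp[other])
            rows.append({"annotation": annotation, "other": other,
                         "t": float(t), "df": len(d) - 1, "p": float(p)})
    return pd.DataFrame(rows)
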