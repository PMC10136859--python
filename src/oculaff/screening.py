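"""Feature screening, correlation pruning, and the pupil-luminance check.

Screening fits, per feature, a linear mixed model with the class level
(arousal, valence, or quadrant) as fixed effect and a participant random
intercept — the repeated-measures structure of many recordings per
participant makes plain ANOVA invalid.  Pairwise class contrasts are
Bonferroni-adjusted.  Feature selection drops the worse-ranked member of
every highly correlated feature pair (|r| > 0.3 by default).  The
luminance check correlates pupil diameter with the video's per-frame V
(brightness) channel to verify that luminance is not driving the pupil
features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .reference import FEATURE_NAMES, FEATURE_SETS


@dataclass
class MLMResult:
    """Mixed-model screening outcome for one feature."""

    feature: str
    p_omnibus: float
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    class_means: dict[str, tuple[float, float]]  # class -> (estimate, SE)
    random_intercept_var: float
    fixed_effects_fallback: bool = False


def bonferroni(pvals, k: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p becomes min(1, p * k).

    ``k`` defaults to the number of comparisons supplied.  Order-preserving
    and capped at 1.
    """
    pvals = list(pvals)
    if k is None:
        k = len(pvals)
    if k < 1:
        raise ValueError("k must be >= 1")
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * k) for p in pvals]


def fit_feature_mlm(values, labels, participants, feature: str = "feature") -> MLMResult:
    """Screen one feature with a participant-random-intercept linear model.

    Fits ``value ~ class`` with a random intercept per participant by
    restricted maximum likelihood, returns the omnibus Wald p-value for the
    class factor, Bonferroni-adjusted pairwise contrasts, and estimated
    class means with standard errors.  If the random-intercept variance
    collapses to (numerically) zero the model is refit as ordinary least
    squares with a warning.
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "cls": np.asarray(labels, object),
                       "pid": np.asarray(participants, object)}).dropna(subset=["y"])
    classes = sorted(df["cls"].unique())
    if len(classes) < 2:
        raise ValueError("screening needs >= 2 classes")
    if df["pid"].nunique() < 2:
        raise ValueError("screening needs >= 2 participants")

    X = pd.get_dummies(df["cls"], drop_first=True, dtype=float)
    X.insert(0, "Intercept", 1.0)
    baseline = classes[0]

    fallback = False
    re_var = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            fit = MixedLM(df["y"].to_numpy(), X.to_numpy(), groups=df["pid"]).fit(reml=True)
            re_var = float(np.squeeze(np.asarray(fit.cov_re)))
            if not np.isfinite(re_var) or re_var < 1e-10:
                fallback = True
        except (np.linalg.LinAlgError, ValueError):
            fallback = True

    if fallback:
        warnings.warn(f"{feature}: singular random-intercept fit; "
                      "falling back to a fixed-effects model")
        import statsmodels.api as sm
        fit = sm.OLS(df["y"].to_numpy(), X.to_numpy()).fit()
        re_var = 0.0

    params = np.asarray(fit.params)[: X.shape[1]]
    cov = np.asarray(fit.cov_params())[: X.shape[1], : X.shape[1]]

    # omnibus Wald test on the class coefficients
    k_dummy = len(classes) - 1
    R = np.zeros((k_dummy, X.shape[1]))
    for i in range(k_dummy):
        R[i, 1 + i] = 1.0
    beta = R @ params
    vmat = R @ cov @ R.T
    stat = float(beta @ np.linalg.solve(vmat, beta))
    p_omnibus = float(stats.chi2.sf(stat, df=k_dummy))

    # class means +/- SE via contrast vectors (intercept + dummy)
    class_means: dict[str, tuple[float, float]] = {}
    cvecs = {}
    for cls in classes:
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        if cls != baseline:
            c[1 + (classes.index(cls) - 1)] = 1.0
        cvecs[cls] = c
        class_means[cls] = (float(c @ params), float(np.sqrt(c @ cov @ c)))

    # pairwise Wald contrasts, Bonferroni-adjusted over all pairs
    pairs = list(combinations(classes, 2))
    raw = []
    for a, b in pairs:
        d = cvecs[a] - cvecs[b]
        se = math.sqrt(d @ cov @ d)
        z = (d @ params) / se
        raw.append(2 * stats.norm.sf(abs(z)))
    adj = bonferroni(raw, k=len(pairs))
    return MLMResult(feature=feature, p_omnibus=p_omnibus,
                     pairwise_p=dict(zip(pairs, adj)), class_means=class_means,
                     random_intercept_var=re_var, fixed_effects_fallback=fallback)


class MixedModelScreener(BaseEstimator):
    """Per-feature mixed-model screening over a feature table.

    ``fit(X, y, groups)`` screens every column of ``X`` (a DataFrame of
    features) against the class labels ``y`` with a participant random
    intercept, populating ``results_`` and ``pvalues_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y, groups):
        results = {}
        for col in X.columns:
            results[col] = fit_feature_mlm(X[col].to_numpy(), y, groups, feature=col)
        self.results_ = results
        self.pvalues_ = pd.Series({c: r.p_omnibus for c, r in results.items()})
        self.significant_ = tuple(self.pvalues_.index[self.pvalues_ < self.alpha])
        return self

    def ranking(self) -> dict[str, float]:
        """feature -> omnibus p (smaller = better discrimination)."""
        return dict(self.pvalues_)


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named predictor set drawn from the 28-feature schema."""

    target: str  # arousal | valence | combined (or custom)
    features: tuple[str, ...]

    def __post_init__(self):
        if self.target in FEATURE_SETS:  # named sets live in the 28-feature schema
            unknown = set(self.features) - set(FEATURE_NAMES)
            if unknown:
                raise ValueError(
                    f"features not in the 28-feature schema: {sorted(unknown)}")

    def __len__(self):
        return len(self.features)


def reference_feature_set(target: str) -> FeatureSetSpec:
    """The published predictor set for a task (sizes 6 / 8 / 7)."""
    return FeatureSetSpec(target=target, features=FEATURE_SETS[target])


def prune_by_correlation(feature_table: pd.DataFrame, candidates,
                         ranking: dict[str, float], r_max: float = 0.3,
                         target: str = "custom") -> FeatureSetSpec:
    """Drop the worse-ranked member of every highly correlated pair.

    Iterates greedily: while any candidate pair has |Pearson r| > ``r_max``,
    remove the feature with the worst rank (largest screening p-value,
    ties broken alphabetically) among features in offending pairs, then
    recompute.  The survivors are returned as a :class:`FeatureSetSpec`;
    the output is always a subset of the candidates.
    """
    kept = [c for c in candidates]
    if not kept:
        return FeatureSetSpec(target=target, features=())
    missing = set(kept) - set(feature_table.columns)
    if missing:
        raise ValueError(f"candidates missing from feature table: {sorted(missing)}")
    while len(kept) > 1:
        corr = feature_table[kept].corr().abs()
        offending = set()
        for a, b in combinations(kept, 2):
            if corr.loc[a, b] > r_max:
                offending.update((a, b))
        if not offending:
            break
        worst = max(offending, key=lambda f: (ranking.get(f, math.inf), f))
        kept.remove(worst)
    return FeatureSetSpec(target=target, features=tuple(kept))


class CorrelationPruner(BaseEstimator):
    """Selector wrapper over :func:`prune_by_correlation`.

    ``fit(X)`` with a ranking (or a fitted :class:`MixedModelScreener`)
    records the surviving columns in ``selected_``; ``transform`` restricts
    a feature table to them.
    """

    def __init__(self, r_max: float = 0.3, target: str = "custom"):
        self.r_max = r_max
        self.target = target

    def fit(self, X: pd.DataFrame, y=None, ranking: dict[str, float] | None = None,
            candidates=None):
        if ranking is None:
            ranking = {c: 0.0 for c in X.columns}
        spec = prune_by_correlation(X, list(candidates or X.columns), ranking,
                                    r_max=self.r_max, target=self.target)
        self.selected_ = spec.features
        self.spec_ = spec
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[list(self.selected_)]

    def get_support(self):
        return self.selected_


# ---------------------------------------------------------------------------
# Pupil-luminance confound check
# ---------------------------------------------------------------------------

CORRELATION_CATEGORIES = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (math.inf, "strong"),
)


@dataclass(frozen=True)
class LuminanceCheckResult:
    r: float
    category: str | None
    n_frames: int


def categorize_correlation(r: float) -> str:
    """Correlation strength category on |r|: <0.2 very weak, <0.4 weak,
    <0.6 moderate, else strong."""
    a = abs(r)
    for bound, name in CORRELATION_CATEGORIES:
        if a < bound or math.isinf(bound):
            return name
    raise AssertionError  # pragma: no cover


def luminance_check(pupil_mm, pupil_t, v_frames, frame_rate_hz: float) -> LuminanceCheckResult:
    """Correlate pupil diameter with the per-frame V (brightness) channel.

    The pupil series (the finer rate) is block-averaged onto the video
    frame intervals before computing the Pearson correlation; frames
    without any valid pupil sample are dropped.  Returns NaN r when either
    series has zero variance.
    """
    pupil = np.asarray(pupil_mm, float)
    t = np.asarray(pupil_t, float)
    v = np.asarray(v_frames, float)
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    frame_idx = np.floor((t - t[0]) * frame_rate_hz).astype(int)
    ok = np.isfinite(pupil) & (frame_idx >= 0) & (frame_idx < len(v))
    sums = np.bincount(frame_idx[ok], weights=pupil[ok], minlength=len(v))
    counts = np.bincount(frame_idx[ok], minlength=len(v))
    have = counts > 0
    if have.sum() < 3:
        return LuminanceCheckResult(r=math.nan, category=None, n_frames=int(have.sum()))
    p_frame = sums[have] / counts[have]
    v_frame = v[have]
    if np.std(p_frame) == 0 or np.std(v_frame) == 0:
        return LuminanceCheckResult(r=math.nan, category=None, n_frames=int(have.sum()))
    r = float(stats.pearsonr(p_frame, v_frame)[0])
    return LuminanceCheckResult(r=r, category=categorize_correlation(r),
                                n_frames=int(have.sum()))
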