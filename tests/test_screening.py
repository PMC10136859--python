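import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculaff.reference import FEATURE_SETS
from oculaff.screening import (CorrelationPruner, MixedModelScreener, bonferroni,
                               categorize_correlation, fit_feature_mlm,
                               luminance_check, prune_by_correlation,
                               reference_feature_set)
from oculaff.simulate import class_profile, generate_recording, luminance_probe


class TestBonferroni:
    @pytest.mark.parametrize("p,k,expected", [
        (0.01, 3, 0.03),
        (0.5, 3, 1.0),
    ])
    def test_scaling_and_cap(self, p, k, expected):
        assert bonferroni([p], k) == [pytest.approx(expected)]

    def test_vector(self):
        assert bonferroni([0.001, 0.02, 0.2], 3) == pytest.approx([0.003, 0.06, 0.6])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_adjusted_at_least_raw_capped_order_preserving(self, ps):
        adj = bonferroni(ps)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p or a == 1.0 for a, p in zip(adj, ps))
        order = np.argsort(ps)
        assert list(np.argsort(np.array(adj)[order])) == sorted(
            range(len(ps)), key=lambda i: adj[order[i]])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)


def _mixed_data(rng, n_part=12, per_class=4, shift=0.0, sigma_b=0.5):
    pids, labs, y = [], [], []
    for p in range(n_part):
        b = rng.normal(0, sigma_b) if sigma_b > 0 else 0.0
        for c, delta in (("A", 0.0), ("B", shift)):
            for _ in range(per_class):
                pids.append(f"p{p}")
                labs.append(c)
                y.append(b + delta + rng.normal())
    return y, labs, pids


class TestMixedModel:
    def test_zero_between_participant_variance_recovers_raw_means(self):
        # balanced design: mixed-model class means equal the raw class means
        # whether or not the random variance collapses to the fallback path
        rng = np.random.default_rng(0)
        y, labs, pids = _mixed_data(rng, sigma_b=0.0, shift=1.0)
        res = fit_feature_mlm(y, labs, pids)
        assert res.random_intercept_var < 0.1
        df = pd.DataFrame({"y": y, "c": labs})
        for cls in ("A", "B"):
            assert res.class_means[cls][0] == pytest.approx(
                df.loc[df["c"] == cls, "y"].mean(), abs=1e-8)

    def test_strong_effect_is_detected(self):
        rng = np.random.default_rng(1)
        y, labs, pids = _mixed_data(rng, n_part=24, shift=1.0)
        res = fit_feature_mlm(y, labs, pids)
        assert res.p_omnibus < 1e-4
        assert res.random_intercept_var > 0
        pair = res.pairwise_p[("A", "B")]
        assert pair <= 1.0 and pair >= res.p_omnibus / 2  # adjusted, same contrast

    def test_adjusted_pairwise_at_least_raw(self):
        rng = np.random.default_rng(2)
        pids, labs, y = [], [], []
        for p in range(10):
            b = rng.normal(0, 0.3)
            for c in ("A", "B", "C"):
                for _ in range(3):
                    pids.append(p)
                    labs.append(c)
                    y.append(b + rng.normal())
        res = fit_feature_mlm(y, labs, pids)
        assert set(res.pairwise_p) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert all(0 <= p <= 1 for p in res.pairwise_p.values())

    def test_screener_over_feature_table(self):
        rng = np.random.default_rng(3)
        y1, labs, pids = _mixed_data(rng, n_part=16, shift=1.5)
        y0, _, _ = _mixed_data(rng, n_part=16, shift=0.0)
        X = pd.DataFrame({"signal": y1, "noise": y0})
        scr = MixedModelScreener().fit(X, labs, pids)
        assert scr.pvalues_["signal"] < 0.01
        assert "signal" in scr.significant_
        assert scr.ranking()["signal"] < scr.ranking()["noise"]


class TestPruning:
    def test_perfectly_correlated_pair_keeps_better_ranked(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        table = pd.DataFrame({"f1": a, "f2": 2 * a + 1, "f3": rng.normal(size=100)})
        spec = prune_by_correlation(table, ["f1", "f2", "f3"],
                                    {"f1": 0.001, "f2": 0.04, "f3": 0.02})
        assert set(spec.features) == {"f1", "f3"}

    def test_uncorrelated_candidates_unchanged(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("abcd"))
        spec = prune_by_correlation(table, list("abcd"), {c: 0.01 for c in "abcd"})
        assert spec.features == ("a", "b", "c", "d")

    def test_empty_candidates_give_empty_set(self):
        spec = prune_by_correlation(pd.DataFrame({"a": [1.0, 2.0]}), [], {})
        assert spec.features == ()

    def test_output_subset_and_rmax_monotonicity(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(300, 3))
        table = pd.DataFrame({
            "a": base[:, 0], "b": base[:, 0] * 0.8 + 0.6 * base[:, 1],
            "c": base[:, 1], "d": base[:, 2]})
        ranking = {"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04}
        sizes = []
        for r_max in (0.05, 0.3, 0.9):
            spec = prune_by_correlation(table, list("abcd"), ranking, r_max=r_max)
            assert set(spec.features) <= {"a", "b", "c", "d"}
            sizes.append(len(spec))
        assert sizes == sorted(sizes)  # lowering r_max never enlarges the set

    def test_pruner_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        X = pd.DataFrame({"f1": a, "f2": a + rng.normal(0, 0.01, 50)})
        pruner = CorrelationPruner().fit(X, ranking={"f1": 0.01, "f2": 0.5})
        assert pruner.selected_ == ("f1",)
        assert list(pruner.transform(X).columns) == ["f1"]

    def test_reference_sets_have_published_sizes(self):
        assert len(reference_feature_set("arousal")) == 6
        assert len(reference_feature_set("valence")) == 8
        assert len(reference_feature_set("combined")) == 7
        for target, feats in FEATURE_SETS.items():
            assert len(set(feats)) == len(feats)


class TestLuminance:
    def test_identical_series_is_strong(self):
        t = np.arange(1000) / 240.0
        rng = np.random.default_rng(0)
        v_frames = rng.normal(size=int(t[-1] * 25) + 1)
        pupil = v_frames[np.floor(t * 25).astype(int)]
        res = luminance_check(pupil, t, v_frames, 25.0)
        assert res.r == pytest.approx(1.0)
        assert res.category == "strong"

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        n = 10_000
        t = np.arange(n) / 240.0
        res = luminance_check(rng.normal(3.5, 0.3, n), t,
                              rng.normal(0.5, 0.1, int(n / 240 * 25) + 1), 25.0)
        assert abs(res.r) < 0.05

    @pytest.mark.parametrize("r,cat", [
        (0.15, "very weak"), (-0.15, "very weak"), (0.3, "weak"),
        (0.45, "moderate"), (0.8, "strong"),
    ])
    def test_categories(self, r, cat):
        assert categorize_correlation(r) == cat

    def test_zero_variance_gives_nan(self):
        t = np.arange(500) / 240.0
        res = luminance_check(np.full(500, 3.5), t, np.full(53, 0.5), 25.0)
        assert math.isnan(res.r) and res.category is None

    def test_probe_coupling_recovered(self):
        rec, _ = generate_recording(class_profile("MAMV"), duration_s=60.0, seed=4)
        v = luminance_probe(rec, coupling=0.45, seed=5)
        res = luminance_check(rec.pupil_mm, rec.t, v, 25.0)
        assert res.category in ("moderate", "weak")
        assert res.r == pytest.approx(0.45, abs=0.12)
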