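import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, ndtr

from tremordiff.diffstats import (
    analyze_pair,
    discrimination_coefficient,
    discrimination_from_summary,
    fit_logistic,
    roc_curve,
    youden_optimal_cutoff,
)


def mann_whitney_auc(scores, labels):
    """Oracle: pairwise rank statistic, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_youden(values, labels, direction=">="):
    """Oracle: scan every possible threshold position exhaustively."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    distinct = np.unique(values)
    candidates = np.concatenate(
        [[-math.inf], (distinct[:-1] + distinct[1:]) / 2.0, [math.inf]]
    )
    best = None
    for c in candidates:
        pred = values >= c if direction == ">=" else values <= c
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        tpr, fpr = tp / (tp + fn), fp / (fp + tn)
        acc = (tp + tn) / labels.size
        key = (tpr - fpr, acc, -fpr, -c)
        if best is None or key > best[0]:
            best = (key, c, tpr, fpr, acc)
    return best[1:]


class TestDiscriminationCoefficient:
    def test_printed_frequency_summary(self):
        res = discrimination_from_summary(5.2, 1.6, 8.1, 2.0)
        assert res.alpha == pytest.approx(2.9 / 3.6)
        assert res.passes_level

    def test_identical_means_zero(self):
        res = discrimination_from_summary(3.0, 0.5, 3.0, 1.5)
        assert res.alpha == 0.0
        assert not res.passes_level

    def test_unit_example(self):
        assert discrimination_from_summary(1.0, 0.5, 0.0, 0.5).alpha == 1.0

    def test_from_values_uses_sample_sd(self):
        a = [1.0, 2.0, 3.0]
        b = [5.0, 6.0, 7.0]
        res = discrimination_coefficient(a, b)
        assert res.alpha == pytest.approx(4.0 / (2 * np.std(a, ddof=1)))
        assert res.n_a == res.n_b == 3

    def test_symmetry(self):
        a = np.random.default_rng(0).normal(0, 1, 30)
        b = np.random.default_rng(1).normal(2, 3, 40)
        assert discrimination_coefficient(a, b).alpha == pytest.approx(
            discrimination_coefficient(b, a).alpha
        )

    @given(
        st.floats(-50, 50),
        st.floats(0.1, 10),
        st.floats(0.01, 5).filter(lambda a: abs(a) > 0.01),
        st.floats(-20, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, mu, sigma, scale, shift):
        rng = np.random.default_rng(7)
        a = rng.normal(mu, sigma, 25)
        b = rng.normal(mu + 1, sigma, 25)
        base = discrimination_coefficient(a, b).alpha
        mapped = discrimination_coefficient(scale * a + shift, scale * b + shift).alpha
        assert mapped == pytest.approx(base, rel=1e-9)

    def test_degenerate_zero_sds(self):
        res = discrimination_coefficient([1.0, 1.0], [1.0, 1.0])
        assert res.alpha == 0.0 and not res.degenerate
        res = discrimination_coefficient([1.0, 1.0], [2.0, 2.0])
        assert math.isinf(res.alpha) and res.degenerate

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            discrimination_coefficient([1.0], [2.0, 3.0])


class TestFitLogistic:
    def test_symmetric_separable_toy(self):
        x = np.tile([-1.0, 1.0], 10)
        y = np.tile([0.0, 1.0], 10)
        fit = fit_logistic(x, y)
        assert fit.separation_detected
        assert fit.beta1 > 0
        assert abs(fit.beta0) < 1e-6 * max(abs(fit.beta1), 1.0)

    def test_null_fit_on_permuted_labels(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=2000)
        y = rng.permutation(np.repeat([0.0, 1.0], 1000))
        fit = fit_logistic(x, y)
        assert fit.converged
        assert abs(fit.beta1) <= 3 * fit.beta1_se

    def test_score_equation_at_optimum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = (rng.uniform(size=400) < expit(0.5 + 1.2 * x)).astype(float)
        fit = fit_logistic(x, y)
        assert fit.converged and not fit.separation_detected
        resid = y - fit.predict_proba(x)
        assert abs(resid.sum()) < 1e-6
        assert abs((resid * x).sum()) < 1e-6

    def test_beats_grid_search_oracle(self):
        x = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        fit = fit_logistic(x, y)

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return np.sum(y * eta - np.logaddexp(0.0, eta))

        grid = np.arange(-5.0, 5.0 + 1e-12, 0.01)
        b0g, b1g = np.meshgrid(grid, grid, indexing="ij")
        eta = b0g[..., None] + b1g[..., None] * x
        ll_grid = np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)
        assert loglik(fit.beta0, fit.beta1) >= ll_grid.max() - 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic([1.0, 2.0], [1.0, 1.0])

    def test_constant_feature_intercept_only(self):
        fit = fit_logistic([2.0, 2.0, 2.0, 2.0], [0.0, 1.0, 1.0, 1.0])
        assert fit.beta1 == 0.0
        assert fit.predict_proba(2.0) == pytest.approx(0.75)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 7, 8, 9], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_curve([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert roc.auc == 0.5

    def test_enumerated_075(self):
        roc = roc_curve([1.0, 3.0, 2.0, 4.0], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        roc = roc_curve(rng.normal(size=50), rng.integers(0, 2, 50))
        assert tuple(roc.roc_points[0]) == (0.0, 0.0)
        assert tuple(roc.roc_points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(roc.roc_points[:, 1]) >= 0)

    def test_auc_equals_mann_whitney_100_random(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.integers(4, 20)
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        base = roc_curve(scores, labels)
        warped = roc_curve(np.exp(scores), labels)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)
        assert np.allclose(warped.roc_points, base.roc_points)

    def test_closed_form_normal_auc(self):
        rng = np.random.default_rng(123)
        mu1, s1, mu2, s2 = 5.2, 1.6, 8.1, 2.0
        n = 10_000
        scores = np.concatenate([rng.normal(mu1, s1, n), rng.normal(mu2, s2, n)])
        labels = np.concatenate([np.zeros(n), np.ones(n)])
        expected = ndtr(abs(mu1 - mu2) / math.hypot(s1, s2))
        assert roc_curve(scores, labels).auc == pytest.approx(expected, abs=0.01)


class TestYoudenCutoff:
    def test_perfectly_separated(self):
        feat = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = youden_optimal_cutoff(feat, labels, feature_values=feat)
        assert res.tpr == 1.0 and res.fpr == 0.0 and res.acc == 1.0
        assert 3.0 < res.cutoff_feature < 7.0

    def test_tie_break_prefers_lower_fpr(self):
        feat = np.array([5.0, 6.0, 6.0, 7.0])
        labels = np.array([0, 0, 1, 1])
        res = youden_optimal_cutoff(feat, labels, feature_values=feat)
        assert res.youden == pytest.approx(0.5)
        assert res.cutoff_feature > 6.0
        assert res.tpr == 0.5 and res.fpr == 0.0

    def test_matches_bruteforce_100_random(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.integers(4, 25)
            feat = rng.integers(0, 8, n).astype(float)
            labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            res = youden_optimal_cutoff(feat, labels, feature_values=feat)
            c, tpr, fpr, acc = brute_force_youden(feat, labels)
            assert res.cutoff_feature == c
            assert (res.tpr, res.fpr, res.acc) == (tpr, fpr, acc)

    def test_decreasing_feature_direction(self):
        feat = np.array([9.0, 8.0, 7.0, 3.0, 2.0, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        scores = -feat  # monotone decreasing in the feature
        res = youden_optimal_cutoff(scores, labels, feature_values=feat)
        assert res.direction == "<="
        assert res.tpr == 1.0 and res.fpr == 0.0
        assert 3.0 < res.cutoff_feature < 7.0

    def test_non_monotone_features_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            youden_optimal_cutoff(
                [0.1, 0.2, 0.3, 0.4],
                [0, 1, 0, 1],
                feature_values=[1.0, 5.0, 2.0, 3.0],
            )


def feature_table(n_subjects=10, n_segments=10, seed=0):
    """Synthetic segment-level table built directly (no signal processing)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        group = "PD" if i < n_subjects // 2 else "ET"
        stage = "S1" if i % 2 == 0 else "S2"
        base = rng.normal(5.0 if group == "PD" else 8.0, 1.5)
        for posture in ("P1", "P2"):
            for s in range(n_segments):
                rows.append(
                    {
                        "subject_id": f"{group}-{i}",
                        "group": group,
                        "stage": stage,
                        "posture": posture,
                        "segment_index": s,
                        "segment_length_s": 30.0,
                        "domfreq_psd": base + rng.normal(0, 0.2),
                    }
                )
    return pd.DataFrame(rows)


class TestAnalyzePair:
    def test_instance_count_is_segments(self):
        table = feature_table(n_subjects=50, n_segments=10)
        disc, roc = analyze_pair(table, "domfreq_psd", ("PD", "ET"), "P2")
        assert disc.n_a + disc.n_b == 500
        assert 0.0 <= roc.auc <= 1.0

    def test_missing_stage_rejected(self):
        table = feature_table(n_subjects=10).drop(columns=["stage"])
        with pytest.raises(ValueError, match="stage"):
            analyze_pair(table, "domfreq_psd", ("PD1", "ET1"), "P2")

    def test_empty_selection_names_filter(self):
        table = feature_table(n_subjects=4)
        table = table[table["group"] != "ET"]
        with pytest.raises(ValueError, match="ET"):
            analyze_pair(table, "domfreq_psd", ("PD", "ET"), "P2")

    def test_probability_and_rank_roc_agree(self):
        table = feature_table(n_subjects=20, seed=3)
        disc, roc = analyze_pair(table, "domfreq_psd", ("PD", "ET"), "P1")
        sub = table[table["posture"] == "P1"]
        raw = sub["domfreq_psd"].to_numpy()
        labels = (sub["group"] == "ET").astype(int).to_numpy()
        rank_roc = roc_curve(raw if roc.beta1 >= 0 else -raw, labels)
        assert roc.auc == pytest.approx(rank_roc.auc, abs=1e-12)

    def test_separated_pair_flagged_with_perfect_roc(self):
        table = feature_table(n_subjects=10, seed=1)
        sub = table.copy()
        sub.loc[sub["group"] == "ET", "domfreq_psd"] += 100.0
        disc, roc = analyze_pair(sub, "domfreq_psd", ("PD", "ET"), "P2")
        assert roc.separation_detected
        assert roc.auc == 1.0
        assert roc.tpr == 1.0 and roc.fpr == 0.0 and roc.acc == 1.0
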