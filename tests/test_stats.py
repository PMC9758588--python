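"""Mixed ANOVA, post hoc t-tests, and cluster permutation inference."""

import numpy as np
import pytest
from scipy import stats as sps

from sampeeg.stats import (
    cluster_test_1samp,
    cluster_test_interaction,
    mixed_anova_2x2,
    posthoc_t,
)


def make_mixed_data(rng, n_per_group=10, within_effect=0.0, between_effect=0.0,
                    interaction=0.0, subject_sd=1.0, noise_sd=1.0):
    scores, groups = [], []
    for g, label in enumerate(("a", "b")):
        sign = 1.0 if g == 0 else -1.0
        for _ in range(n_per_group):
            subj = rng.normal(0, subject_sd)
            y1 = subj + sign * between_effect / 2 + rng.normal(0, noise_sd)
            y2 = (
                subj + sign * between_effect / 2 + within_effect
                + sign * interaction / 2 + rng.normal(0, noise_sd)
            )
            scores.append([y1, y2])
            groups.append(label)
    return np.array(scores), np.array(groups)


class TestMixedAnova:
    def test_additive_construction_has_zero_interaction(self):
        """Identical within-contrast noise in both groups makes the
        interaction numerator exactly zero."""
        rng = np.random.default_rng(0)
        base = rng.standard_normal((6, 2))
        scores = np.vstack([base + 1.0, base - 2.0])  # pure between shift
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova_2x2(scores, groups)
        assert res.interaction.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_hand_computed_sums_of_squares(self):
        """Balanced 3+3 example worked through the classical SS formulas."""
        scores = np.array(
            [[3.0, 5.0], [4.0, 7.0], [5.0, 6.0], [2.0, 3.0], [3.0, 3.0], [4.0, 5.0]]
        )
        groups = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
        res = mixed_anova_2x2(scores, groups)

        # independent classical computation on sums/differences
        d = scores[:, 1] - scores[:, 0]
        m = scores.mean(axis=1)
        d1, d2 = d[:3], d[3:]
        m1, m2 = m[:3], m[3:]
        # within main: unweighted mean of the group d-means over its pooled SE
        se_d = np.sqrt(
            (np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2)) / 4
        )
        t_within = np.mean([d1.mean(), d2.mean()]) / (se_d * np.sqrt((1 / 3 + 1 / 3) / 4))
        t_inter = (d1.mean() - d2.mean()) / (se_d * np.sqrt(1 / 3 + 1 / 3))
        se_m = np.sqrt(
            (np.sum((m1 - m1.mean()) ** 2) + np.sum((m2 - m2.mean()) ** 2)) / 4
        )
        t_between = (m1.mean() - m2.mean()) / (se_m * np.sqrt(1 / 3 + 1 / 3))
        assert res.within.F == pytest.approx(t_within**2)
        assert res.interaction.F == pytest.approx(t_inter**2)
        assert res.between.F == pytest.approx(t_between**2)
        assert res.within.df1 == 1 and res.within.df2 == 4

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        scores, groups = make_mixed_data(rng, n_per_group=8, within_effect=0.5,
                                         interaction=0.8)
        res = mixed_anova_2x2(scores, groups)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(16), 2),
                "within": np.tile(["w1", "w2"], 16),
                "group": np.repeat(groups, 2),
                "y": scores.ravel(),
            }
        )
        pg = pingouin.mixed_anova(
            data=long, dv="y", within="within", subject="subject", between="group"
        ).set_index("Source")
        assert res.between.F == pytest.approx(pg.loc["group", "F"], rel=1e-6)
        assert res.within.F == pytest.approx(pg.loc["within", "F"], rel=1e-6)
        assert res.interaction.F == pytest.approx(pg.loc["Interaction", "F"], rel=1e-6)
        assert res.interaction.eta_p2 == pytest.approx(pg.loc["Interaction", "np2"], rel=1e-6)

    def test_pooled_within_reduces_to_paired_t(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal((12, 2)) + np.array([0.0, 0.4])
        res = mixed_anova_2x2(scores, np.array(["only"] * 12))
        t, p = sps.ttest_rel(scores[:, 1], scores[:, 0])
        assert res.within.F == pytest.approx(t**2)
        assert res.within.p == pytest.approx(p)
        assert res.between is None and res.interaction is None

    def test_interaction_type_i_error_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            scores, groups = make_mixed_data(rng, n_per_group=6)
            res = mixed_anova_2x2(scores, groups)
            rejections += res.interaction.p < 0.05
        assert 0.037 <= rejections / n_sim <= 0.063

    def test_validation(self):
        with pytest.raises(ValueError):
            mixed_anova_2x2(np.array([[1.0, np.nan], [2.0, 3.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            mixed_anova_2x2(np.ones((4, 2)), ["a", "b", "c", "c"])


class TestPosthocT:
    def test_identical_conditions(self):
        a = np.arange(10.0)
        res = posthoc_t([("same", a, a.copy())])
        assert res[0].t == 0.0
        assert res[0].p_corrected == 1.0

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal(15)
        b = a + rng.normal(0, 1, 15) * 0.01 + 0.001
        res = posthoc_t([("x", a, b), ("y", a, b)])
        raw = sps.ttest_rel(a, b).pvalue
        assert res[0].p_corrected == min(1.0, 2 * raw)
        big = posthoc_t([("x", a, a + rng.normal(0, 1, 15)), ("y", a, b)])
        assert all(r.p_corrected <= 1.0 for r in big)

    def test_power_for_one_sd_shift(self):
        """Planted 1 SD mean shift, n = 20: analytic power ~ 0.988."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            diff = rng.normal(1.0, 1.0, 20)
            res = posthoc_t([("shift", diff, np.zeros(20))], correction="none")
            hits += res[0].p_corrected < 0.05
        assert hits / n_sim >= 0.96

    def test_zero_variance_flagged(self):
        a = np.ones(8)
        res = posthoc_t([("flat", a + 1.0, a)])
        assert res[0].flagged
        assert np.isinf(res[0].t)


class TestCluster1Samp:
    def test_default_permutation_count(self):
        import inspect

        sig = inspect.signature(cluster_test_1samp)
        assert sig.parameters["n_perm"].default == 10000

    def test_saturated_effect_single_full_cluster_at_min_p(self):
        rng = np.random.default_rng(12)
        X = 1.0 + 0.1 * rng.standard_normal((20, 80))
        res = cluster_test_1samp(X, n_perm=500, rng=rng)
        assert len(res.clusters) == 1
        assert (res.clusters[0].start_idx, res.clusters[0].end_idx) == (0, 79)
        assert res.p_values[0] == res.min_attainable_p == 1 / 501

    def test_reproducible_under_seed(self):
        X = np.random.default_rng(13).standard_normal((10, 50)) + 0.3
        r1 = cluster_test_1samp(X, n_perm=300, rng=np.random.default_rng(5))
        r2 = cluster_test_1samp(X, n_perm=300, rng=np.random.default_rng(5))
        assert r1.p_values == r2.p_values
        assert r1.clusters == r2.clusters

    def test_invariant_to_unit_rescaling(self):
        X = np.random.default_rng(14).standard_normal((12, 60)) + 0.4
        r1 = cluster_test_1samp(X, n_perm=300, rng=np.random.default_rng(6))
        r2 = cluster_test_1samp(3.7 * X, n_perm=300, rng=np.random.default_rng(6))
        assert r1.p_values == r2.p_values

    def test_matches_mne_cluster_identification(self):
        """Observed clusters (bounds and masses) agree with the reference
        implementation at the same cluster-forming threshold."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(15)
        X = rng.standard_normal((15, 100))
        X[:, 30:45] += 0.9
        n = X.shape[0]
        thr = sps.t.ppf(1 - 0.025, n - 1)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            X, threshold=thr, n_permutations=100, tail=0, seed=1, out_type="mask",
            verbose="error",
        )
        ours = cluster_test_1samp(X, n_perm=100, rng=np.random.default_rng(1))
        mne_spans = sorted((c[0].start, c[0].stop - 1) for c in clusters)
        our_spans = sorted((c.start_idx, c.end_idx) for c in ours.clusters)
        assert our_spans == mne_spans
        for c in ours.clusters:
            assert c.mass == pytest.approx(t_obs[c.start_idx : c.end_idx + 1].sum())

    def test_validation(self):
        with pytest.raises(ValueError):
            cluster_test_1samp(np.ones((3, 10)))
        with pytest.warns(UserWarning):
            cluster_test_1samp(np.random.default_rng(0).standard_normal((6, 10)), n_perm=50)


class TestClusterInteraction:
    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(16)
        n = 12
        X = rng.standard_normal((2 * n, 120))
        X[:n, 40:70] += 1.5  # boost only in group 1
        groups = np.array(["g1"] * n + ["g2"] * n)
        res = cluster_test_interaction(X, groups, n_perm=300, rng=rng)
        sig = [c for c, p in zip(res.clusters, res.p_values) if p <= 0.05]
        assert any(c.start_idx <= 70 and c.end_idx >= 40 for c in sig)

    def test_common_shift_is_not_an_interaction(self):
        """An equal within effect in both groups must not trigger the
        interaction test beyond its nominal rate."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(100):
            X = rng.standard_normal((16, 60))
            X[:, 20:40] += 1.0  # same shift in everyone
            groups = np.array(["g1"] * 8 + ["g2"] * 8)
            res = cluster_test_interaction(X, groups, n_perm=200, rng=rng)
            rejections += any(p <= 0.05 for p in res.p_values)
        assert rejections / 100 <= 0.12

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(18)
        rejections = 0
        for _ in range(100):
            X = rng.standard_normal((16, 60))
            X[:8, 20:40] += 1.2
            groups = rng.permutation(np.array(["g1"] * 8 + ["g2"] * 8))
            res = cluster_test_interaction(X, groups, n_perm=200, rng=rng)
            rejections += any(p <= 0.05 for p in res.p_values)
        # label shuffling destroys the group effect; only chance rejections remain
        assert rejections / 100 <= 0.15

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            cluster_test_interaction(
                np.random.default_rng(0).standard_normal((4, 10)),
                ["a", "a", "b", "b"],
            )
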