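import numpy as np
import pytest

from gutshift.enrichment import (kruskal_gate, lda_effect_size, lefse,
                                 paired_wilcoxon)
from gutshift.simulate import enrichment_benchmark, null_two_group_benchmark

from conftest import make_table, paired_metadata


def two_group_table(rng, n_features=20, n_per_group=6, planted=None, fold=4.0):
    """Log-normal table; optionally multiply ``planted`` rows in group 2."""
    x = rng.lognormal(3, 0.5, size=(n_features, 2 * n_per_group))
    if planted:
        for i in planted:
            x[i, n_per_group:] *= fold
    labels = ["g1"] * n_per_group + ["g2"] * n_per_group
    return make_table(x), labels


class TestKruskalGate:
    def test_constant_feature_gets_p_one(self):
        table = make_table([[2.0] * 8, [1, 2, 3, 4, 5, 6, 7, 8]])
        pvals, passed = kruskal_gate(table, ["a"] * 4 + ["b"] * 4)
        assert pvals["f0"] == 1.0
        assert "f0" not in passed

    def test_identical_groups_not_passed(self):
        row = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        table = make_table([row])
        pvals, passed = kruskal_gate(table, ["a"] * 3 + ["b"] * 3)
        assert "f0" not in passed

    def test_null_features_pass_near_alpha_rate(self):
        passes = []
        for seed in range(10):
            table, labels = null_two_group_benchmark(seed, n_features=100)
            _, passed = kruskal_gate(table, labels, alpha=0.05)
            passes.append(len(passed))
        assert 2 <= np.mean(passes) <= 9  # nominal 5 of 100

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, size=(1, 12))
        labels = ["a"] * 6 + ["b"] * 6
        p1, _ = kruskal_gate(make_table(x), labels)
        p2, _ = kruskal_gate(make_table(np.log1p(x)), labels)
        assert p1["f0"] == pytest.approx(p2["f0"])


class TestLdaEffectSize:
    def test_no_separation_scores_zero(self):
        # identical group means and variances for every feature: the second
        # feature repeats the same values in both groups so per-sample
        # normalisation cannot separate the classes either
        rng = np.random.default_rng(1)
        other = rng.lognormal(3, 1, 6)
        x = np.vstack([np.full(12, 100.0) + np.tile(rng.normal(0, 1e-6, 6), 2),
                       np.tile(other, 2)])
        table = make_table(x)
        labels = ["a"] * 6 + ["b"] * 6
        scores = lda_effect_size(table, labels, {"f0"})
        assert abs(scores["f0"]) == pytest.approx(0.0, abs=0.05)

    def test_planted_fold_change_scores_above_two(self):
        rng = np.random.default_rng(2)
        table, labels = two_group_table(rng, planted=[0], fold=4.0)
        _, passed = kruskal_gate(table, labels)
        scores = lda_effect_size(table, labels, {"f0"})
        assert abs(scores["f0"]) >= 2.0

    def test_relabeling_flips_sign_preserves_magnitude(self):
        rng = np.random.default_rng(3)
        table, labels = two_group_table(rng, planted=[2], fold=3.0)
        s1 = lda_effect_size(table, labels, {"f2"}, positive_group="g2")
        s2 = lda_effect_size(table, labels, {"f2"}, positive_group="g1")
        assert s1["f2"] == pytest.approx(-s2["f2"], rel=1e-9)

    def test_direction_parallel_to_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from gutshift.enrichment import _lda_direction
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 3))
        y = np.array([0] * 20 + [1] * 20)
        x[y == 1] += [1.0, 0.5, 0.0]
        w = _lda_direction(x, y, ridge=1e-12)
        coef = LinearDiscriminantAnalysis().fit(x, y).coef_.ravel()
        cos = np.dot(w, coef) / (np.linalg.norm(w) * np.linalg.norm(coef))
        assert abs(cos) == pytest.approx(1.0, abs=1e-6)

    def test_fewer_than_two_per_group_raises(self):
        table = make_table(np.ones((2, 3)) * [[1, 2, 3]])
        with pytest.raises(ValueError, match="at least 2"):
            lda_effect_size(table, ["a", "a", "b"], {"f0"})


class TestLefse:
    def test_single_feature_complete_separation(self):
        # 4 + 4 completely separated: exact permutation p = 2/70 < 0.05
        table = make_table([[100.0, 200, 300, 400, 1000, 1100, 1200, 1300]])
        res = lefse(table, ["pre"] * 4 + ["post"] * 4, positive_group="post")
        assert res[0].significant
        assert res[0].enriched_group == "post"
        assert res[0].lda_score > 0

    def test_recovery_of_planted_features(self):
        table, labels, planted = enrichment_benchmark(seed=0)
        res = lefse(table, labels, positive_group="post")
        recovered = {r.feature_id for r in res
                     if r.significant and r.enriched_group == "post"}
        assert len(recovered & set(planted)) >= 4

    def test_sorted_by_absolute_score(self):
        rng = np.random.default_rng(6)
        table, labels = two_group_table(rng, planted=[0, 5], fold=6.0)
        res = lefse(table, labels)
        scored = [r for r in res if np.isfinite(r.lda_score)]
        mags = [abs(r.lda_score) for r in scored]
        assert mags == sorted(mags, reverse=True)

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(7)
        table, labels = two_group_table(rng, planted=[1], fold=5.0)
        res1 = lefse(table, labels)
        perm = rng.permutation(table.n_samples)
        shuffled = make_table(table.values[:, perm],
                              sample_ids=[table.sample_ids[i] for i in perm])
        res2 = lefse(shuffled, [labels[i] for i in perm])
        by_id1 = {r.feature_id: r for r in res1}
        by_id2 = {r.feature_id: r for r in res2}
        for fid in by_id1:
            assert by_id1[fid].kruskal_p == pytest.approx(by_id2[fid].kruskal_p)
            if np.isfinite(by_id1[fid].lda_score):
                assert by_id1[fid].lda_score == pytest.approx(
                    by_id2[fid].lda_score, abs=1e-8)

    def test_bootstrap_mode_close_to_plain_score(self):
        rng = np.random.default_rng(8)
        table, labels = two_group_table(rng, n_per_group=10, planted=[0], fold=8.0)
        plain = lefse(table, labels)
        boot = lefse(table, labels, bootstrap=30, seed=5)
        s_plain = {r.feature_id: r.lda_score for r in plain if r.significant}
        s_boot = {r.feature_id: r.lda_score for r in boot if r.significant}
        assert "f0" in s_plain and "f0" in s_boot
        assert s_boot["f0"] == pytest.approx(s_plain["f0"], abs=0.5)


class TestPairedWilcoxon:
    def _cohort(self, diffs):
        n = len(diffs)
        metadata = paired_metadata(n)
        pre = np.full(n, 10.0)
        post = pre + np.asarray(diffs, dtype=float)
        ids = [f"A{i+1:02d}_pre" for i in range(n)] + \
              [f"A{i+1:02d}_post" for i in range(n)]
        table = make_table(np.concatenate([pre, post])[None, :], sample_ids=ids)
        return table, metadata

    def test_all_positive_differences_exact_p(self):
        table, metadata = self._cohort([1, 2, 0.5, 3, 1.5, 2.5])
        res = paired_wilcoxon(table, metadata, "f0")
        assert res.n_pairs == 6
        assert res.p_value == pytest.approx(2 / 64)
        assert res.direction == "increase"

    def test_zero_differences_dropped_from_n(self):
        table, metadata = self._cohort([0, 0, 1, 2, 3, -0.5, 4])
        res = paired_wilcoxon(table, metadata, "f0")
        assert res.n_pairs == 5

    def test_all_zero_differences_degenerate(self):
        table, metadata = self._cohort([0, 0, 0, 0])
        res = paired_wilcoxon(table, metadata, "f0")
        assert res.degenerate and res.p_value == 1.0

    def test_decrease_direction(self):
        table, metadata = self._cohort([-1, -2, -3, -0.5, -1.5, 1.0])
        res = paired_wilcoxon(table, metadata, "f0")
        assert res.direction == "decrease"

    def test_missing_feature_raises(self):
        table, metadata = self._cohort([1, 2, 3])
        with pytest.raises(KeyError):
            paired_wilcoxon(table, metadata, "nope")
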