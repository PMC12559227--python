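import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from gutshift.beta import (DistanceMatrix, bray_curtis, distance_matrix,
                           matched_distances, permanova)
from gutshift.profiles import ProfileError

from conftest import make_table, paired_metadata


class TestBrayCurtis:
    def test_identity_is_zero(self):
        x = [3.0, 1.0, 2.0]
        assert bray_curtis(x, x) == 0.0

    def test_disjoint_supports_give_one(self):
        assert bray_curtis([1, 0, 2, 0], [0, 3, 0, 1]) == 1.0

    def test_hand_case(self):
        assert bray_curtis([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(0, 5, 8)
            y = rng.uniform(0, 5, 8)
            d = bray_curtis(x, y)
            assert d == pytest.approx(bray_curtis(y, x))
            assert 0.0 <= d <= 1.0

    def test_both_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])


class TestDistanceMatrix:
    def test_identical_samples_off_diagonal_zero(self):
        table = make_table([[5.0, 5.0], [2.0, 2.0]])
        dm = distance_matrix(table)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_shape_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.uniform(0, 3, size=(6, 3)))
        dm = distance_matrix(table)
        assert dm.d.shape == (3, 3)
        np.testing.assert_allclose(dm.d, dm.d.T)
        np.testing.assert_allclose(np.diag(dm.d), 0.0)

    def test_entries_match_pairwise_calls(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 3, size=(10, 4))
        table = make_table(values)
        dm = distance_matrix(table)
        norm = values / values.sum(axis=0)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert dm.d[i, j] == pytest.approx(
                        bray_curtis(norm[:, i], norm[:, j]), abs=1e-12)

    def test_zero_total_sample_named(self):
        table = make_table([[1.0, 0.0], [1.0, 0.0]], sample_ids=["ok", "bad"])
        with pytest.raises(ProfileError, match="bad"):
            distance_matrix(table)


class TestMatchedDistances:
    def test_post_equals_pre_gives_zero(self):
        metadata = paired_metadata(3)
        values = np.random.default_rng(0).uniform(0, 2, size=(5, 3))
        table = make_table(np.hstack([values, values]),
                           sample_ids=[f"A{i+1:02d}_pre" for i in range(3)]
                                      + [f"A{i+1:02d}_post" for i in range(3)])
        dm = distance_matrix(table)
        records, skipped = matched_distances(dm, metadata)
        assert len(records) == 3 and not skipped
        assert all(r.distance == pytest.approx(0.0, abs=1e-12) for r in records)

    def test_hand_built_pairs_match_direct_calls(self):
        metadata = paired_metadata(2)
        values = np.random.default_rng(5).uniform(0, 2, size=(6, 4))
        ids = ["A01_pre", "A01_post", "A02_pre", "A02_post"]
        table = make_table(values, sample_ids=ids)
        dm = distance_matrix(table)
        records, _ = matched_distances(dm, metadata)
        norm = values / values.sum(axis=0)
        assert records[0].distance == pytest.approx(
            bray_curtis(norm[:, 0], norm[:, 1]))
        assert records[1].distance == pytest.approx(
            bray_curtis(norm[:, 2], norm[:, 3]))

    def test_missing_timepoint_goes_to_skip_report(self):
        metadata = paired_metadata(2)[:3]  # A02 lost its post sample
        table = make_table(np.random.default_rng(1).uniform(1, 2, (4, 3)),
                           sample_ids=["A01_pre", "A01_post", "A02_pre"])
        dm = distance_matrix(table)
        records, skipped = matched_distances(dm, metadata)
        assert [r.subject_id for r in records] == ["A01"]
        assert skipped == ["A02"]

    def test_duplicate_timepoint_sample_raises(self):
        metadata = paired_metadata(1)
        metadata[1].timepoint = metadata[0].timepoint  # two "pre" samples
        dm = distance_matrix(make_table(
            np.random.default_rng(0).uniform(1, 2, (3, 2)),
            sample_ids=["A01_pre", "A01_post"]))
        with pytest.raises(ValueError, match="two samples"):
            matched_distances(dm, metadata)


def _random_dm(rng, n=12, features=10):
    x = rng.lognormal(0, 1, size=(n, features))
    d = squareform(pdist(x / x.sum(1, keepdims=True), "braycurtis"))
    np.fill_diagonal(d, 0)
    return DistanceMatrix([f"s{i}" for i in range(n)], d)


class TestPermanova:
    def test_single_group_raises(self):
        dm = _random_dm(np.random.default_rng(0))
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dm, ["a"] * 12)

    def test_small_group_raises(self):
        dm = _random_dm(np.random.default_rng(0))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a"] * 11 + ["b"])

    def test_two_tight_clusters_give_minimum_p(self):
        rng = np.random.default_rng(7)
        a = np.abs(np.tile([10, 1, 1, 1], (8, 1)) + rng.normal(0, 0.01, (8, 4)))
        b = np.abs(np.tile([1, 1, 1, 10], (8, 1)) + rng.normal(0, 0.01, (8, 4)))
        x = np.vstack([a, b])
        d = squareform(pdist(x, "braycurtis"))
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(16)], d)
        res = permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_invariant_to_group_renaming(self):
        dm = _random_dm(np.random.default_rng(3))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(dm, labels, 499, seed=11)
        r2 = permanova(dm, ["post" if l == "a" else "pre" for l in labels],
                       499, seed=11)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.p_value == r2.p_value

    def test_pseudo_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        dm = _random_dm(np.random.default_rng(5), n=14)
        labels = ["a"] * 7 + ["b"] * 7
        mine = permanova(dm, labels, 99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(dm.d, dm.sample_ids),
                              grouping=labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"])

    def test_euclidean_univariate_recovers_anova_f(self):
        # PERMANOVA pseudo-F on Euclidean distances of 1-D data is the
        # classical one-way ANOVA F.
        rng = np.random.default_rng(9)
        a, b, c = rng.normal(0, 1, 5), rng.normal(1, 1, 6), rng.normal(2, 1, 4)
        x = np.concatenate([a, b, c])
        d = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix([f"s{i}" for i in range(len(x))], d)
        labels = ["a"] * 5 + ["b"] * 6 + ["c"] * 4
        res = permanova(dm, labels, 99, seed=0)
        f_classic = stats.f_oneway(a, b, c).statistic
        assert res.pseudo_F == pytest.approx(f_classic, rel=1e-10)

    def test_p_estimator_never_zero_and_seed_reproducible(self):
        dm = _random_dm(np.random.default_rng(13))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(dm, labels, 199, seed=42)
        r2 = permanova(dm, labels, 199, seed=42)
        assert r1.p_value == r2.p_value > 0
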