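"""Clustering, silhouette and the minimum-size selection rule."""

import numpy as np
import pytest

import caretraj as ct
from caretraj.cluster import agglomerate, cut, pam_medoids, select_solution, silhouette
from caretraj.om import DistanceMatrix


def dmat(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix([f"p{i}" for i in range(len(values))], values)


@pytest.fixture
def toy4():
    # pairs {0,1} at distance 1 and {2,3} at distance 2, cross >= 5
    d = np.full((4, 4), 10.0)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 1.0
    d[2, 3] = d[3, 2] = 2.0
    return dmat(d)


@pytest.fixture
def three_groups():
    """Well-separated groups of sizes 40 / 40 / 2."""
    rng = np.random.default_rng(0)
    n = 82
    centers = np.array([0.0] * 40 + [50.0] * 40 + [100.0] * 2)
    x = centers + rng.uniform(-1, 1, size=n)
    d = np.abs(x[:, None] - x[None, :])
    return dmat(d)


class TestAgglomerate:
    def test_merge_order_on_toy(self, toy4):
        tree = agglomerate(toy4, "complete")
        assert set(tree[0, :2].astype(int)) == {0, 1}
        assert set(tree[1, :2].astype(int)) == {2, 3}
        assert tree[0, 2] == 1.0 and tree[1, 2] == 2.0

    def test_two_points(self):
        d = dmat([[0.0, 3.0], [3.0, 0.0]])
        tree = agglomerate(d, "complete")
        assert tree.shape == (1, 4) and tree[0, 2] == 3.0

    def test_heights_nondecreasing(self, retained_small, cost_model):
        kept, _ = retained_small
        dm = ct.pairwise_distance_matrix(kept.subset(range(80)), cost_model)
        for method in ("complete", "ward"):
            tree = agglomerate(dm, method)
            assert np.all(np.diff(tree[:, 2]) >= -1e-9)

    def test_unknown_linkage(self, toy4):
        with pytest.raises(ValueError):
            agglomerate(toy4, "single")


class TestCut:
    def test_toy_partition(self, toy4):
        tree = agglomerate(toy4, "complete")
        sol = cut(tree, 2, toy4)
        assert sol.labels[0] == sol.labels[1]
        assert sol.labels[2] == sol.labels[3]
        assert sol.labels[0] != sol.labels[2]

    def test_extremes(self, toy4):
        tree = agglomerate(toy4, "complete")
        assert cut(tree, 1).k == 1
        assert np.all(cut(tree, 1).labels == 1)
        assert cut(tree, 4).k == 4  # singletons
        with pytest.raises(ValueError):
            cut(tree, 0)
        with pytest.raises(ValueError):
            cut(tree, 5)

    def test_nested_partitions(self, three_groups):
        tree = agglomerate(three_groups, "complete")
        l2, l3 = cut(tree, 2).labels, cut(tree, 3).labels
        # k=3 refines k=2: points sharing a k=3 cluster share the k=2 cluster
        for g in np.unique(l3):
            assert len(np.unique(l2[l3 == g])) == 1

    def test_sizes_nonincreasing(self, three_groups):
        tree = agglomerate(three_groups, "complete")
        for k in range(2, 8):
            sol = cut(tree, k)
            assert np.all(np.diff(sol.sizes) <= 0)
            assert sol.sizes.sum() == three_groups.n


class TestSilhouette:
    def test_hand_computed_example(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        widths, asw = silhouette(dmat(d), [1, 1, 2, 2])
        assert np.allclose(widths, 0.9)  # (10 - 1) / 10
        assert asw == pytest.approx(0.9)

    def test_mixed_labels_score_poorly(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 1.0
        _, asw = silhouette(dmat(d), [1, 2, 1, 2])
        assert asw <= 0

    def test_singleton_scores_zero(self, toy4):
        widths, _ = silhouette(toy4, [1, 1, 2, 3])
        assert widths[3] == 0.0

    def test_single_cluster_rejected(self, toy4):
        with pytest.raises(ValueError):
            silhouette(toy4, [1, 1, 1, 1])

    def test_matches_naive_and_sklearn(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.uniform(0, 10, size=(20, 2))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
            labels = rng.integers(1, 4, size=20)
            if len(np.unique(labels)) < 2:
                continue
            widths, asw = silhouette(dmat(d), labels)
            naive = []
            for i in range(20):
                same = (labels == labels[i]) & (np.arange(20) != i)
                if same.sum() == 0:
                    naive.append(0.0)
                    continue
                a = d[i, same].mean()
                b = min(
                    d[i, labels == g].mean() for g in np.unique(labels) if g != labels[i]
                )
                naive.append((b - a) / max(a, b))
            assert np.allclose(widths, naive)
            assert np.allclose(widths, silhouette_samples(d, labels, metric="precomputed"))


class TestPAM:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.5, 20), rng.normal(30, 0.5, 15)])
        d = np.abs(x[:, None] - x[None, :])
        sol = pam_medoids(dmat(d), 2, seed=0)
        assert sol.k == 2
        assert len(set(sol.labels[:20])) == 1
        assert len(set(sol.labels[20:])) == 1

    def test_k_equals_n(self, toy4):
        sol = pam_medoids(toy4, 4, seed=0)
        assert sol.k == 4
        assert sorted(sol.sizes.tolist()) == [1, 1, 1, 1]

    def test_matches_exhaustive_search(self):
        from itertools import combinations

        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, size=(6, 2))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        sol = pam_medoids(dmat(d), 2, seed=0)
        cost = 0.0
        for g in np.unique(sol.labels):
            sub = d[np.ix_(sol.labels == g, sol.labels == g)]
            cost += sub.sum(axis=0).min()  # best medoid within the cluster
        best = min(
            sum(d[:, list(m)].min(axis=1)) for m in combinations(range(6), 2)
        )
        assert cost == pytest.approx(best, abs=1e-9)

    def test_deterministic_given_seed(self, three_groups):
        a = pam_medoids(three_groups, 3, seed=5)
        b = pam_medoids(three_groups, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestSelection:
    def test_size_threshold(self):
        assert int(np.ceil(0.011 * 2271)) == 25

    def test_size_rule_on_toy(self, three_groups):
        tree = agglomerate(three_groups, "complete")
        # threshold ceil(0.011 * 82) = 1: the 2-member group is admissible
        sol = select_solution(tree, three_groups, k_range=range(2, 4), min_frac=0.011)
        assert sol.k == 3
        # threshold ceil(0.05 * 82) = 5: the 2-member group fails the rule
        sol = select_solution(tree, three_groups, k_range=range(2, 4), min_frac=0.05)
        assert sol.k == 2

    def test_asw_curve_reported(self, three_groups):
        tree = agglomerate(three_groups, "complete")
        sol = select_solution(tree, three_groups, k_range=range(2, 6), min_frac=0.011)
        assert set(sol.asw_curve) == {2, 3, 4, 5}
        assert all(-1 <= v <= 1 for v in sol.asw_curve.values())

    def test_fallback_to_k2(self):
        # three points: no k in range can satisfy an impossible size rule
        d = dmat([[0, 1, 9], [1, 0, 9], [9, 9, 0]])
        tree = agglomerate(d, "complete")
        sol = select_solution(tree, d, k_range=range(2, 3), min_frac=0.9)
        assert sol.k == 2


class TestRecovery:
    def test_archetypes_recovered_on_subsample(self):
        """Complete linkage at k=6 recovers the latent archetypes (ARI >= 0.8)."""
        from sklearn.metrics import adjusted_rand_score

        cfg = ct.default_config(n_raw=800, seed=42)
        cohort, latent = ct.generate_cohort(cfg)
        kept, retained, _ = ct.filter_min_observations(cohort)
        id_to_lab = dict(zip(cohort.ids, latent))
        lab = np.array([id_to_lab[i] for i in kept.ids])
        dm = ct.pairwise_distance_matrix(kept, ct.build_cost_model(kept.specs))
        sol = cut(agglomerate(dm, "complete"), 6, dm)
        assert adjusted_rand_score(lab, sol.labels) >= 0.8
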