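import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from smcoloc.clustering import ClusterParams, cluster_centroid, density_cluster
from smcoloc.locdata import make_table


def brute_force_cluster(points, eps, npt):
    """Independent oracle: explicit neighbour matrix + connected components.

    Returns (set of frozensets of member indices, frozenset of noise indices).
    """
    n = len(points)
    if n == 0:
        return set(), frozenset()
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    adj = d <= eps  # includes self
    core = adj.sum(axis=1) >= npt
    core_adj = adj & core[:, None] & core[None, :]
    n_comp, comp = connected_components(csr_matrix(core_adj), directed=False)
    labels = np.full(n, -1)
    labels[core] = comp[core]
    for i in np.flatnonzero(~core):
        core_nbs = np.flatnonzero(adj[i] & core)
        if len(core_nbs):
            labels[i] = labels[core_nbs[0]]  # lowest-indexed core neighbour
    clusters = {
        frozenset(np.flatnonzero(labels == lab))
        for lab in np.unique(labels) if lab >= 0
    }
    return clusters, frozenset(np.flatnonzero(labels == -1))


def as_partition(clusters, noise):
    return ({frozenset(c.member_indices) for c in clusters}, frozenset(noise))


def table_from(points):
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) == 0:
        return make_table(x=[], y=[], z=[])
    return make_table(x=points[:, 0], y=points[:, 1], z=points[:, 2])


class TestDensityCluster:
    def test_empty_input(self):
        clusters, noise = density_cluster(table_from(np.empty((0, 3))))
        assert clusters == [] and noise == []

    def test_pair_clusters_isolated_point_is_noise(self):
        pts = [(0, 0, 0), (10, 0, 0), (1000, 0, 0)]
        clusters, noise = density_cluster(table_from(pts), ClusterParams(25.0, 2))
        assert as_partition(clusters, noise) == ({frozenset({0, 1})}, frozenset({2}))

    def test_chain_expands_across_eps_links(self):
        pts = [(0, 0, 0), (20, 0, 0), (40, 0, 0)]
        clusters, noise = density_cluster(table_from(pts), ClusterParams(25.0, 2))
        assert as_partition(clusters, noise) == ({frozenset({0, 1, 2})}, frozenset())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClusterParams(eps=25.0, npt=0)
        with pytest.raises(ValueError):
            ClusterParams(eps=0.0, npt=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = rng.integers(0, 200)
            scale = rng.choice([60.0, 150.0, 400.0])
            pts = rng.uniform(0, scale, size=(n, 3))
            clusters, noise = density_cluster(table_from(pts), ClusterParams(25.0, 2))
            assert as_partition(clusters, noise) == brute_force_cluster(pts, 25.0, 2)

    def test_matches_sklearn_on_core_and_noise_structure(self, rng):
        # independent library cross-check: sklearn uses the same core
        # convention (neighbour count includes the point itself)
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        pts = rng.uniform(0, 200, size=(150, 3))
        model = sklearn_cluster.DBSCAN(eps=25.0, min_samples=2).fit(pts)
        clusters, noise = density_cluster(table_from(pts), ClusterParams(25.0, 2))
        assert frozenset(np.flatnonzero(model.labels_ == -1)) == frozenset(noise)
        assert len(set(model.labels_) - {-1}) == len(clusters)

    def test_partition_covers_input_exactly_once(self, rng):
        pts = rng.uniform(0, 120, size=(80, 3))
        clusters, noise = density_cluster(table_from(pts), ClusterParams(25.0, 2))
        seen = sorted(i for c in clusters for i in c.member_indices) + sorted(noise)
        assert sorted(seen) == list(range(80))

    def test_npt_one_leaves_no_noise(self, rng):
        pts = rng.uniform(0, 500, size=(60, 3))
        clusters, noise = density_cluster(table_from(pts), ClusterParams(25.0, 1))
        assert noise == []
        assert sum(c.n_spots for c in clusters) == 60

    def test_permutation_invariance_of_structure(self, rng):
        pts = rng.uniform(0, 150, size=(100, 3))
        perm = rng.permutation(100)
        c1, n1 = density_cluster(table_from(pts), ClusterParams(25.0, 2))
        c2, n2 = density_cluster(table_from(pts[perm]), ClusterParams(25.0, 2))
        # noise set and cluster count invariant under row permutation
        assert frozenset(perm[i] for i in n2) == frozenset(n1)
        assert len(c2) == len(c1)

    def test_centroids_are_member_means(self):
        pts = [(0, 0, 0), (10, 0, 0)]
        clusters, _ = density_cluster(table_from(pts), ClusterParams(25.0, 2))
        assert clusters[0].centroid == pytest.approx((5.0, 0.0, 0.0))
        assert clusters[0].n_spots == 2


class TestClusterCentroid:
    def test_single_member(self):
        np.testing.assert_allclose(cluster_centroid([(0, 0, 0)]), [0, 0, 0])

    def test_mean_of_two(self):
        np.testing.assert_allclose(
            cluster_centroid([(0, 0, 0), (10, 0, 0)]), [5, 0, 0]
        )

    def test_translation_equivariance(self, rng):
        members = rng.normal(size=(12, 3))
        v = np.array([3.0, -4.0, 5.0])
        np.testing.assert_allclose(
            cluster_centroid(members + v), cluster_centroid(members) + v, atol=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_centroid(np.empty((0, 3)))
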