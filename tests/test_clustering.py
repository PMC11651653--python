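"""Feature construction, PCA, spectral clustering, silhouettes, composition."""

import numpy as np
import pytest
from scipy.stats import norm, special_ortho_group
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from icpop import clustering
from icpop.signals import OutcomeAverages


def _averages(n, L=193, seed=0):
    rng = np.random.default_rng(seed)
    return OutcomeAverages(hit_avg=rng.random((n, L)), miss_avg=rng.random((n, L)), L=L)


def brute_force_silhouette(X, labels):
    """Literal re-statement of the silhouette definitions: per sample, mean
    distance to own cluster (a), minimum mean distance to any other cluster
    (b), s = (b - a)/max(a, b); 0 for singletons."""
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s


def planted_blobs(k, n_per=25, dim=9, sep=12.0, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = sep * rng.standard_normal((k, dim))
    X = np.vstack([c + noise * rng.standard_normal((n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestBuildFeatures:
    def test_386_columns_at_L193(self):
        X = clustering.build_features(_averages(10))
        assert X.shape == (10, 386)

    def test_toy_L5_gives_10_columns(self):
        X = clustering.build_features(_averages(4, L=5))
        assert X.shape == (4, 10)

    def test_zero_traces_give_zero_matrix(self):
        a = OutcomeAverages(hit_avg=np.zeros((3, 5)), miss_avg=np.zeros((3, 5)), L=5)
        assert not clustering.build_features(a).any()

    def test_hit_precedes_miss(self):
        a = OutcomeAverages(hit_avg=np.ones((1, 3)), miss_avg=2 * np.ones((1, 3)), L=3)
        np.testing.assert_array_equal(clustering.build_features(a)[0], [1, 1, 1, 2, 2, 2])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="L"):
            clustering.build_features([_averages(2, L=5), _averages(2, L=7)])


class TestPCA:
    def test_planar_data_has_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((2, 10))
        X = rng.standard_normal((50, 2)) @ basis
        _, evr, _ = clustering.pca_reduce(X, n_components=5)
        assert evr[:2].sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(evr[2:] < 1e-10)

    def test_rotation_invariance_of_spectrum(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 8))
        R = special_ortho_group.rvs(8, random_state=3)
        _, evr1, _ = clustering.pca_reduce(X, 5)
        _, evr2, _ = clustering.pca_reduce(X @ R, 5)
        np.testing.assert_allclose(evr1, evr2, atol=1e-10)

    def test_reconstruction_error_equals_discarded_variance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 12))
        scores, evr, pca = clustering.pca_reduce(X, 5)
        recon = scores @ pca.components_ + pca.mean_
        resid_var = np.sum((X - recon) ** 2) / np.sum((X - X.mean(axis=0)) ** 2)
        assert resid_var == pytest.approx(1.0 - evr.sum(), abs=1e-10)

    def test_excess_components_rejected(self):
        with pytest.raises(ValueError):
            clustering.pca_reduce(np.zeros((5, 4)), n_components=6)


class TestSpectralCluster:
    def test_separated_blobs_recovered(self):
        X, truth = planted_blobs(2, n_per=30, seed=5)
        labels = clustering.spectral_cluster(X, n_neighbors=10, n_clusters=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_points_co_clustered(self):
        X, _ = planted_blobs(3, n_per=10, seed=6)
        XX = np.vstack([X, X])
        labels = clustering.spectral_cluster(XX, n_neighbors=8, n_clusters=3, seed=0)
        np.testing.assert_array_equal(labels[: len(X)], labels[len(X) :])

    def test_seed_determinism(self):
        X, _ = planted_blobs(3, seed=7)
        a = clustering.spectral_cluster(X, 10, 3, seed=4)
        b = clustering.spectral_cluster(X, 10, 3, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_disconnected_graph_raises_with_guidance(self):
        X, _ = planted_blobs(5, n_per=10, sep=100.0, noise=0.01, seed=8)
        with pytest.raises(ValueError, match="n_neighbors"):
            clustering.spectral_cluster(X, n_neighbors=2, n_clusters=2, seed=0)


class TestSilhouette:
    def test_duplicate_clusters_score_one(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        labels = np.array([0, 0, 1, 1])
        mean_s, br = clustering.silhouette_mean(X, labels)
        assert mean_s == pytest.approx(1.0)
        np.testing.assert_allclose(br.a, 0.0)

    def test_hand_evaluated_example(self):
        # 1-D points {0,1} vs {10,11}: s(0) = (10.5 - 1)/10.5
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        _, br = clustering.silhouette_mean(X, np.array([0, 0, 1, 1]))
        assert br.s[0] == pytest.approx((10.5 - 1) / 10.5)
        assert br.a[0] == pytest.approx(1.0)
        assert br.b[0] == pytest.approx(10.5)

    @pytest.mark.parametrize("n,k,seed", [(50, 3, 0), (100, 5, 1), (30, 2, 2)])
    def test_matches_brute_force_to_1e12(self, n, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 4))
        labels = rng.integers(0, k, size=n)
        mean_s, br = clustering.silhouette_mean(X, labels)
        ref = brute_force_silhouette(X, labels)
        np.testing.assert_allclose(br.s, ref, atol=1e-12)
        # independent library cross-check
        np.testing.assert_allclose(br.s, silhouette_samples(X, labels), atol=1e-9)

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 3))
        labels = rng.integers(0, 4, size=60)
        m1, br = clustering.silhouette_mean(X, labels)
        assert np.all(br.s >= -1) and np.all(br.s <= 1)
        perm = (labels + 1) % 4  # relabel clusters
        m2, _ = clustering.silhouette_mean(X, perm)
        assert m1 == pytest.approx(m2)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            clustering.silhouette_mean(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestHyperparameterSearch:
    def test_planted_k4_selected(self):
        X, truth = planted_blobs(4, n_per=20, seed=9)
        model = clustering.hyperparameter_search(
            X, n_neighbors_grid=(5, 10, 15), n_clusters_grid=range(2, 9), n_components=9, seed=0
        )
        assert model.n_clusters == 4
        assert adjusted_rand_score(truth, model.labels) == 1.0
        assert len(model.grid) == 3 * 7

    def test_single_cell_grid_returned(self):
        X, _ = planted_blobs(3, seed=10)
        model = clustering.hyperparameter_search(
            X, n_neighbors_grid=(10,), n_clusters_grid=(3,), seed=0
        )
        assert (model.n_neighbors, model.n_clusters) == (10, 3)

    def test_tie_breaks_to_fewer_neighbors(self):
        # two clean blobs: any neighbour count that keeps the graph connected
        # yields the same labels, hence tied silhouettes -> smallest nn wins
        X, _ = planted_blobs(2, n_per=15, seed=11)
        model = clustering.hyperparameter_search(
            X, n_neighbors_grid=(5, 10, 15), n_clusters_grid=(2,), n_components=2, seed=0
        )
        grid = model.grid
        assert grid["mean_silhouette"].nunique() == 1  # genuine tie
        assert model.n_neighbors == 5

    def test_all_cells_failing_raises(self):
        X, _ = planted_blobs(6, n_per=5, sep=100.0, noise=0.01, seed=12)
        with pytest.raises(ValueError, match="n_neighbors"):
            clustering.hyperparameter_search(
                X, n_neighbors_grid=(1,), n_clusters_grid=(2,), n_components=5, seed=0
            )


class TestEndToEndRecovery:
    @pytest.mark.parametrize("k", [3, 5, 10])
    def test_prototype_profiles_recovered(self, k):
        """Neurons drawn from K prototype profiles at 10 % noise are
        recovered with ARI >= 0.9 and the search selects the true K."""
        rng = np.random.default_rng(k)
        L = 193
        t = np.linspace(-2, 5, L)
        protos = [
            np.sin(2 * np.pi * (t + 2) / 7.0 * (i % 5 + 1)) * (1 + i // 5)
            for i in range(k)
        ]
        rows, truth = [], []
        for i, p in enumerate(protos):
            for _ in range(20):
                hit = p + 0.1 * rng.standard_normal(L)
                miss = 0.5 * p + 0.1 * rng.standard_normal(L)
                rows.append(np.hstack([hit, miss]))
                truth.append(i)
        X = np.vstack(rows)
        model = clustering.hyperparameter_search(
            X,
            n_neighbors_grid=(10, 20),
            n_clusters_grid=range(2, 13),
            n_components=9,
            seed=0,
        )
        assert model.n_clusters == k
        assert adjusted_rand_score(truth, model.labels) >= 0.9


class TestCompositionTest:
    def test_population_ratio_gives_half_and_p_one(self):
        labels = np.zeros(100, dtype=int)
        labels[50:] = 1
        lesioned = np.zeros(100, dtype=bool)
        # both clusters at exactly the population ratio 0.4
        lesioned[:20] = True
        lesioned[50:70] = True
        res = clustering.composition_test(labels, lesioned)
        np.testing.assert_allclose(res["normalized_prop"], 0.5)
        np.testing.assert_allclose(res["z"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_hand_computed_one_proportion_z(self):
        # cluster of 100 with 60 lesioned against population rate 0.36
        n_pop = 1000
        lesioned = np.zeros(n_pop, dtype=bool)
        lesioned[:360] = True
        labels = np.ones(n_pop, dtype=int)
        labels[:60] = 0  # cluster 0: 60 lesioned
        labels[360:400] = 0  # plus 40 non-lesioned -> 100 members
        res = clustering.composition_test(labels, lesioned).set_index("cluster_id")
        p_pop = 0.36
        z_ref = (0.6 - p_pop) / np.sqrt(p_pop * (1 - p_pop) / 100)
        assert res.loc[0, "z"] == pytest.approx(z_ref)
        assert res.loc[0, "p"] == pytest.approx(2 * norm.sf(abs(z_ref)))

    def test_single_group_population_rejected(self):
        with pytest.raises(ValueError):
            clustering.composition_test(np.zeros(10, dtype=int), np.ones(10, dtype=bool))
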