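import itertools

import numpy as np
import pytest

from regenrich.qtc import (
    QTClustering,
    jackknife_correlation,
    jackknife_correlation_matrix,
    qt_cluster,
)


def leave_one_out_pearsons(x, y):
    out = []
    for j in range(len(x)):
        keep = np.ones(len(x), dtype=bool)
        keep[j] = False
        out.append(np.corrcoef(x[keep], y[keep])[0, 1])
    return out


class TestJackknifeCorrelation:
    def test_self_correlation_is_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        assert jackknife_correlation(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        assert jackknife_correlation(x, -x) == pytest.approx(-1.0)

    def test_outlier_case_matches_explicit_enumeration(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        expected = min(leave_one_out_pearsons(x, y))
        assert jackknife_correlation(x, y) == pytest.approx(expected)

    def test_constant_after_deletion_rejected(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])  # deleting last -> constant
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="constant"):
            jackknife_correlation(x, y)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matrix_agrees_with_pairwise_function(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 10))
        J = jackknife_correlation_matrix(X)
        for i, j in itertools.combinations(range(8), 2):
            assert J[i, j] == pytest.approx(jackknife_correlation(X[i], X[j]))
            assert J[i, j] == J[j, i]


def exhaustive_qt_oracle(J, cutoff, min_size):
    """Enumerate all admissible subsets, extract largest-first.

    Admissible: min pairwise jackknife correlation >= cutoff.  Ties on
    size resolve by the same preferences as the greedy extraction: the
    subset containing the smallest gene index (seed order), then the
    highest minimum pairwise similarity (the growth objective), then
    lexicographically.
    """
    n = J.shape[0]
    alive = list(range(n))
    clusters = []
    while len(alive) >= min_size:
        best = None
        for size in range(len(alive), min_size - 1, -1):
            candidates = [
                c for c in itertools.combinations(alive, size)
                if all(J[a, b] >= cutoff for a, b in itertools.combinations(c, 2))
            ]
            if candidates:
                def min_sim(c):
                    return min(J[a, b] for a, b in itertools.combinations(c, 2))

                best = min(candidates, key=lambda c: (c[0], -min_sim(c), c))
                break
        if best is None:
            break
        clusters.append(set(best))
        alive = [i for i in alive if i not in best]
    return clusters


def blocky_instance(rng, n_genes=10, n_samples=10):
    """Correlated blocks plus free genes: the structure QTC is used on."""
    X = np.zeros((n_genes, n_samples))
    i = 0
    while i < n_genes:
        size = int(rng.integers(1, 5))
        size = min(size, n_genes - i)
        latent = rng.normal(size=n_samples)
        for k in range(size):
            X[i + k] = latent + rng.normal(scale=0.5, size=n_samples)
        i += size
    return X


class TestQTCluster:
    def test_defaults_match_analysis_parameters(self):
        est = QTClustering()
        assert est.similarity_cutoff == 0.4
        assert est.min_size == 15

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="min_size"):
            QTClustering(min_size=1).fit(np.random.default_rng(0).normal(size=(5, 6)))

    def test_no_pair_reaches_cutoff_gives_empty_result(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 40))  # long profiles: correlations near 0
        clusters = qt_cluster(X, similarity_cutoff=0.95, min_size=2)
        assert clusters == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        X = blocky_instance(rng, n_genes=int(rng.integers(6, 13)))
        J = jackknife_correlation_matrix(
            (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        )
        expected = exhaustive_qt_oracle(J, 0.4, 2)
        got = [set(map(int, c.members))
               for c in qt_cluster(X, similarity_cutoff=0.4, min_size=2)]
        assert got == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_diameter_mode_matches_oracle_too(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = blocky_instance(rng, n_genes=int(rng.integers(6, 13)))
        J = jackknife_correlation_matrix(
            (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        )
        expected = exhaustive_qt_oracle(J, 0.4, 2)
        got = [set(map(int, c.members))
               for c in qt_cluster(X, similarity_cutoff=0.6, min_size=2,
                                   cutoff_as="diameter")]
        assert got == expected

    def test_planted_cluster_recovered_exactly(self):
        rng = np.random.default_rng(42)
        n_samples = 30
        latent = rng.normal(size=n_samples)
        planted = latent + rng.normal(scale=0.3, size=(20, n_samples))
        noise = rng.normal(size=(30, n_samples))
        X = np.vstack([planted, noise])
        clusters = qt_cluster(X, similarity_cutoff=0.4, min_size=15)
        assert len(clusters) == 1
        assert set(map(int, clusters[0].members)) == set(range(20))

    def test_clusters_disjoint_and_satisfy_cutoff_post_hoc(self):
        rng = np.random.default_rng(8)
        X = blocky_instance(rng, n_genes=20, n_samples=12)
        est = QTClustering(similarity_cutoff=0.4, min_size=3).fit(X)
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        J = jackknife_correlation_matrix(Xs)
        seen = set()
        for c in est.clusters_:
            members = set(map(int, c.members))
            assert not members & seen
            seen |= members
            for a, b in itertools.combinations(sorted(members), 2):
                assert J[a, b] >= 0.4

    def test_labels_consistent_with_clusters(self):
        rng = np.random.default_rng(9)
        X = blocky_instance(rng, n_genes=15, n_samples=12)
        est = QTClustering(similarity_cutoff=0.4, min_size=3).fit(X)
        for k, c in enumerate(est.clusters_):
            for m in c.members:
                assert est.labels_[int(m)] == k
        unclustered = set(range(15)) - {
            int(m) for c in est.clusters_ for m in c.members
        }
        for i in unclustered:
            assert est.labels_[i] == -1
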