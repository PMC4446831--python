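import numpy as np
import pytest
from scipy.special import gammaln

from regenrich.enrichment import (
    fisher_enrichment,
    gene_list_overlap,
    resampling_enrichment,
)

from conftest import make_binding


def log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k, M, K, q):
    """Independent log-gamma tail summation P(X >= k)."""
    total = 0.0
    for x in range(max(k, 0), min(K, q) + 1):
        if q - x > M - K:
            continue
        total += np.exp(log_binom(K, x) + log_binom(M - K, q - x) - log_binom(M, q))
    return min(total, 1.0)


def random_binding(rng, n_genes, rate=0.4, max_peaks=3):
    genes = [f"g{i}" for i in range(n_genes)]
    counts = np.where(
        rng.random(n_genes) < rate, rng.integers(1, max_peaks + 1, n_genes), 0
    )
    return make_binding(genes, {"F": counts.tolist()}), genes


class TestFisher:
    def test_small_exact_case(self):
        # universe 5, 3 bound; query 2 both bound -> C(3,2)/C(5,2) = 0.3
        bm = make_binding(list("abcde"), {"F": [1, 1, 1, 0, 0]})
        res = fisher_enrichment(bm, ["a", "b"], "F")
        assert res.fisher_p == pytest.approx(0.3, abs=1e-12)

    def test_zero_bound_query_gives_p_one(self):
        bm = make_binding(list("abcde"), {"F": [1, 1, 1, 0, 0]})
        assert fisher_enrichment(bm, ["d", "e"], "F").fisher_p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_tail_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bm, genes = random_binding(rng, int(rng.integers(20, 120)))
        q = int(rng.integers(2, len(genes) // 2))
        query = list(rng.choice(genes, size=q, replace=False))
        res = fisher_enrichment(bm, query, "F")
        expected = hypergeom_upper_tail(
            res.n_bound_query, res.universe_size, res.n_bound_universe, q
        )
        assert res.fisher_p == pytest.approx(expected, abs=1e-12)

    def test_query_outside_universe_rejected(self):
        bm = make_binding(["a"], {"F": [1]})
        with pytest.raises(ValueError, match="zz"):
            fisher_enrichment(bm, ["zz"], "F")


class TestResampling:
    def test_default_resample_count(self):
        import inspect

        sig = inspect.signature(resampling_enrichment)
        assert sig.parameters["n_resamples"].default == 100_000

    def test_constant_statistic_gives_p_one(self):
        bm = make_binding([f"g{i}" for i in range(30)], {"F": [1] * 30})
        res = resampling_enrichment(bm, [f"g{i}" for i in range(5)], "F",
                                    n_resamples=500, seed=0)
        assert res.resampling_p_bound == pytest.approx(1.0)
        assert res.resampling_p_peaks == pytest.approx(1.0)

    def test_exclusively_bound_query_hits_floor(self):
        counts = [1] * 5 + [0] * 195
        bm = make_binding([f"g{i}" for i in range(200)], {"F": counts})
        res = resampling_enrichment(bm, [f"g{i}" for i in range(5)], "F",
                                    n_resamples=2000, seed=1)
        assert res.resampling_p_bound <= 2 / 2001

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        bm, genes = random_binding(rng, 100)
        query = genes[:20]
        r1 = resampling_enrichment(bm, query, "F", n_resamples=1000, seed=5)
        r2 = resampling_enrichment(bm, query, "F", n_resamples=1000, seed=5)
        assert r1.resampling_p_bound == r2.resampling_p_bound
        assert r1.resampling_p_peaks == r2.resampling_p_peaks

    def test_null_samples_retained_for_plotting(self):
        rng = np.random.default_rng(12)
        bm, genes = random_binding(rng, 60)
        res = resampling_enrichment(bm, genes[:15], "F", n_resamples=300,
                                    seed=2, keep_null=True)
        assert len(res.null_bound_counts) == 300
        assert len(res.null_peak_totals) == 300
        # p recomputable from the retained null draws
        p = (1 + int((res.null_bound_counts >= res.n_bound_query).sum())) / 301
        assert p == res.resampling_p_bound

    def test_p_respects_add_one_floor(self):
        rng = np.random.default_rng(10)
        bm, genes = random_binding(rng, 50)
        res = resampling_enrichment(bm, genes[:10], "F", n_resamples=200, seed=0)
        for p in (res.resampling_p_bound, res.resampling_p_peaks):
            assert 1 / 201 <= p <= 1.0

    def test_concordant_with_fisher_on_random_instances(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(11)
        fisher_ps, resamp_ps = [], []
        for _ in range(25):
            bm, genes = random_binding(rng, 80)
            q = int(rng.integers(5, 30))
            query = list(rng.choice(genes, size=q, replace=False))
            res = resampling_enrichment(bm, query, "F", n_resamples=2000,
                                        seed=int(rng.integers(2**31)))
            fisher_ps.append(res.fisher_p)
            resamp_ps.append(res.resampling_p_bound)
        rho = spearmanr(-np.log10(fisher_ps), -np.log10(resamp_ps)).statistic
        assert rho > 0.95


class TestGeneListOverlap:
    def test_identical_lists_extreme_p(self):
        universe = [f"g{i}" for i in range(1000)]
        a = universe[:10]
        overlap, p = gene_list_overlap(a, a, universe)
        assert overlap == 10
        assert p < 1e-20

    def test_disjoint_lists_give_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        _, p = gene_list_overlap(universe[:10], universe[50:60], universe)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_tail_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(30, 150))
        universe = [f"g{i}" for i in range(M)]
        a = list(rng.choice(universe, size=int(rng.integers(5, M // 2)), replace=False))
        b = list(rng.choice(universe, size=int(rng.integers(5, M // 2)), replace=False))
        overlap, p = gene_list_overlap(a, b, universe)
        assert overlap == len(set(a) & set(b))
        assert p == pytest.approx(
            hypergeom_upper_tail(overlap, M, len(b), len(a)), abs=1e-12
        )

    def test_membership_violation_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            gene_list_overlap(["x"], ["a"], ["a", "b"])
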