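"""Promoter-binding enrichment tests for gene signatures.

Two complementary routes, run per (signature, factor) pair:

* a one-tailed Fisher's exact test on the 2x2 bound/unbound x in/out-of-
  query table (hypergeometric upper tail, enrichment direction only), and
* a resampling test drawing many random gene lists of the query's size
  from the universe and comparing both the number of bound promoters and
  the total peak count against the null draws (empirical add-one p).

:func:`gene_list_overlap` applies the same hypergeometric tail to plain
gene-list intersections (GO-style term or ortholog-target enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .promoters import BindingMatrix

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "resampling_enrichment",
    "gene_list_overlap",
]


@dataclass
class EnrichmentResult:
    factor: str
    query_size: int
    n_bound_query: int
    n_bound_universe: int
    universe_size: int
    total_peaks_query: int = 0
    fisher_p: float = 1.0
    resampling_p_bound: float | None = None
    resampling_p_peaks: float | None = None
    n_resamples: int = 0
    seed: int | None = None
    null_bound_counts: np.ndarray | None = field(default=None, repr=False)
    null_peak_totals: np.ndarray | None = field(default=None, repr=False)

    def summary_row(self) -> dict:
        return {
            "factor": self.factor,
            "query_size": self.query_size,
            "n_bound_query": self.n_bound_query,
            "n_bound_universe": self.n_bound_universe,
            "universe_size": self.universe_size,
            "total_peaks_query": self.total_peaks_query,
            "fisher_p": self.fisher_p,
            "resampling_p_bound": self.resampling_p_bound,
            "resampling_p_peaks": self.resampling_p_peaks,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


def _query_indices(binding: BindingMatrix, query: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(binding.genes)}
    missing = [g for g in query if g not in index]
    if missing:
        raise ValueError(f"query genes absent from universe: {missing[:10]}")
    return np.array([index[g] for g in query], dtype=np.int64)


def fisher_enrichment(
    binding: BindingMatrix, query: list[str], factor: str
) -> EnrichmentResult:
    """One-tailed Fisher's exact test for promoter-binding enrichment.

    p = P(X >= n_bound_query) with X ~ Hypergeometric(universe_size,
    n_bound_universe, query_size); the universe is every gene in the
    binding matrix.
    """
    idx = _query_indices(binding, query)
    counts = binding.peak_count[factor].values
    bound = counts > 0
    M = len(bound)
    K = int(bound.sum())
    q = len(idx)
    k = int(bound[idx].sum())
    p = float(hypergeom.sf(k - 1, M, K, q))
    return EnrichmentResult(
        factor=factor,
        query_size=q,
        n_bound_query=k,
        n_bound_universe=K,
        universe_size=M,
        total_peaks_query=int(counts[idx].sum()),
        fisher_p=min(p, 1.0),
    )


def resampling_enrichment(
    binding: BindingMatrix,
    query: list[str],
    factor: str,
    n_resamples: int = 100_000,
    seed: int = 0,
    keep_null: bool = False,
) -> EnrichmentResult:
    """Dual-statistic resampling enrichment test against random gene lists.

    Draws ``n_resamples`` gene lists of the query's size uniformly without
    replacement from the universe and compares (a) the bound-promoter count
    and (b) the total peak count against the observed values.  Empirical
    p-values use the add-one convention (1 + #{null >= observed}) /
    (n_resamples + 1), so they are never zero; ties count toward the tail.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    result = fisher_enrichment(binding, query, factor)
    M, q = result.universe_size, result.query_size
    if q > M:
        raise ValueError("query larger than universe")
    counts = binding.peak_count[factor].values.astype(np.int64)
    bound = (counts > 0).astype(np.int64)

    rng = np.random.default_rng(seed)
    exceed_bound = 0
    exceed_peaks = 0
    null_bound = np.empty(n_resamples, dtype=np.int64) if keep_null else None
    null_peaks = np.empty(n_resamples, dtype=np.int64) if keep_null else None
    chunk = max(1, min(n_resamples, int(4e6 // max(M, 1)) or 1))
    done = 0
    while done < n_resamples:
        c = min(chunk, n_resamples - done)
        keys = rng.random((c, M))
        picks = np.argpartition(keys, q - 1, axis=1)[:, :q]
        b = bound[picks].sum(axis=1)
        t = counts[picks].sum(axis=1)
        exceed_bound += int((b >= result.n_bound_query).sum())
        exceed_peaks += int((t >= result.total_peaks_query).sum())
        if keep_null:
            null_bound[done : done + c] = b
            null_peaks[done : done + c] = t
        done += c

    result.resampling_p_bound = (1 + exceed_bound) / (n_resamples + 1)
    result.resampling_p_peaks = (1 + exceed_peaks) / (n_resamples + 1)
    result.n_resamples = n_resamples
    result.seed = seed
    if keep_null:
        result.null_bound_counts = null_bound
        result.null_peak_totals = null_peaks
    return result


def gene_list_overlap(
    list_a: list[str], list_b: list[str], universe: list[str]
) -> tuple[int, float]:
    """Overlap of two gene lists and its hypergeometric upper-tail p-value.

    p = P(X >= |A n B|) with X ~ Hypergeometric(|universe|, |B|, |A|).
    """
    uni = set(universe)
    for name, lst in (("list_a", list_a), ("list_b", list_b)):
        bad = [g for g in lst if g not in uni]
        if bad:
            raise ValueError(f"{name} genes outside universe: {bad[:10]}")
    a, b = set(list_a), set(list_b)
    overlap = len(a & b)
    p = float(hypergeom.sf(overlap - 1, len(uni), len(b), len(a)))
    return overlap, min(p, 1.0)
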