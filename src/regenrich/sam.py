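"""Two-class Significance Analysis of Microarrays with permutation FDR.

The relative-difference statistic for gene *i* is

    d_i = (mean_2i - mean_1i) / (s_i + s0)

with ``s_i`` the pooled standard error of the mean difference and ``s0`` a
small positive fudge factor chosen (Tusher-style) to minimise the
coefficient of variation of ``d`` across strata of ``s_i``.  Significance
is declared against expected order statistics averaged over label
permutations; the threshold ``delta`` is the smallest value whose
permutation-estimated FDR is at or below the target (the pipeline default
target is 0: no permuted configuration may produce as many calls).

:class:`SAMSelector` packages the procedure as a scikit-learn style
feature selector (``fit(X, y)`` with samples in rows); the module-level
functions mirror the selector for matrix-centric use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix

__all__ = [
    "SAMResult",
    "SAMSelector",
    "compute_d_statistics",
    "estimate_s0",
    "sam_significant_genes",
]


@dataclass
class SAMResult:
    genes: list[str]
    d: np.ndarray
    s0: float
    delta: float
    significant_up: list[str]
    significant_down: list[str]
    estimated_fdr: float
    n_permutations: int
    seed: int
    expected_d: np.ndarray = field(default=None, repr=False)  # sorted scale

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.d, kind="mergesort")
        rank_of = np.empty(len(self.d), dtype=int)
        rank_of[order] = np.arange(len(self.d))
        up = set(self.significant_up)
        down = set(self.significant_down)
        direction = [
            "up" if g in up else ("down" if g in down else "") for g in self.genes
        ]
        return pd.DataFrame(
            {
                "gene": self.genes,
                "d": self.d,
                "expected_d": self.expected_d[rank_of],
                "significant": [bool(x) for x in direction],
                "direction": direction,
            }
        )


def _group_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean difference (group2 - group1) and pooled SE of it.

    X is genes x samples; y boolean with True marking group 2.
    """
    n2 = int(y.sum())
    n1 = int((~y).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    m2 = X[:, y].mean(axis=1)
    m1 = X[:, ~y].mean(axis=1)
    ss = ((X[:, y] - m2[:, None]) ** 2).sum(axis=1) + (
        (X[:, ~y] - m1[:, None]) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s


def compute_d_statistics(
    X: np.ndarray | ExpressionMatrix, y: np.ndarray | str, s0: float
) -> np.ndarray:
    """Relative difference d = (mean2 - mean1) / (s + s0), per gene."""
    X, y, _ = _coerce(X, y)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    r, s = _group_stats(X, y)
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError(
            "zero-variance gene(s) with s0 = 0; supply s0 > 0 (see estimate_s0)"
        )
    return r / denom


def estimate_s0(
    X: np.ndarray | ExpressionMatrix,
    y: np.ndarray | str,
    percentile_step: int = 5,
    n_strata: int = 100,
) -> float:
    """Pick s0 from the percentile grid of {s_i} minimising the CV of d.

    Candidates are the 0, 5, ..., 100th percentiles of the per-gene pooled
    standard errors.  For each candidate, genes are binned into quantile
    strata of s_i, the median absolute deviation of d is taken per stratum,
    and the candidate minimising the coefficient of variation of those MADs
    wins; ties break toward the smallest grid index.
    """
    X, y, _ = _coerce(X, y)
    if X.shape[0] < 10:
        raise ValueError("need >= 10 genes to estimate s0")
    r, s = _group_stats(X, y)
    grid = np.percentile(s, np.arange(0, 101, percentile_step))
    n_strata = min(n_strata, max(2, X.shape[0] // 5))
    # quantile strata of s_i, fixed across candidates
    edges = np.quantile(s, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_strata - 1)

    best = (np.inf, 0)
    for idx, alpha in enumerate(grid):
        denom = s + alpha
        if np.any(denom == 0):
            continue
        d = r / denom
        mads = np.array(
            [
                np.median(np.abs(d[strata == j] - np.median(d[strata == j])))
                for j in range(n_strata)
                if np.any(strata == j)
            ]
        )
        mean = mads.mean()
        cv = mads.std() / mean if mean > 0 else 0.0
        if cv < best[0] - 1e-12:
            best = (cv, idx)
    return float(grid[best[1]])


def _permutation_matrix(
    n: int, n2: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (P, n) matrix of group-2 assignments, exhaustive when small."""
    total = comb(n, n2, exact=True)
    if total <= n_permutations:
        rows = np.zeros((total, n), dtype=bool)
        for p, idx in enumerate(itertools.combinations(range(n), n2)):
            rows[p, list(idx)] = True
        return rows
    rows = np.zeros((n_permutations, n), dtype=bool)
    for p in range(n_permutations):
        rows[p, rng.choice(n, size=n2, replace=False)] = True
    return rows


def _permuted_d(X: np.ndarray, B: np.ndarray, s0: float) -> np.ndarray:
    """d statistics for every permutation row of B, fully vectorised."""
    n = X.shape[1]
    n2 = int(B[0].sum())
    n1 = n - n2
    tot = X.sum(axis=1, keepdims=True)  # (m, 1)
    ssq = (X**2).sum(axis=1, keepdims=True)
    sum2 = X @ B.T  # (m, P)
    sum1 = tot - sum2
    ss_within = ssq - sum1**2 / n1 - sum2**2 / n2
    ss_within = np.maximum(ss_within, 0.0)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss_within / (n - 2))
    return (sum2 / n2 - sum1 / n1) / (s + s0)


def _coerce(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accept (ndarray genes x samples, bool labels) or (ExpressionMatrix, group)."""
    if isinstance(X, ExpressionMatrix):
        genes = X.genes
        if isinstance(y, str):
            y = X.group_mask(y)
        X = X.values.values.astype(float)
    else:
        X = np.asarray(X, dtype=float)
        genes = [str(i) for i in range(X.shape[0])]
        y = np.asarray(y, dtype=bool)
    if y.shape[0] != X.shape[1]:
        raise ValueError("labels length must equal number of samples")
    return X, y, genes


def sam_significant_genes(
    X: np.ndarray | ExpressionMatrix,
    y: np.ndarray | str,
    n_permutations: int = 1000,
    target_fdr: float = 0.0,
    seed: int = 0,
    s0: float | None = None,
    fdr_summary: str = "mean",
) -> SAMResult:
    """Run the full SAM procedure and return calls at the chosen delta.

    ``y`` may be a boolean sample mask (True = test group) or, with an
    :class:`ExpressionMatrix`, a group label tested one-vs-rest.  FDR at a
    candidate delta is ``pi0 * summary(permuted false calls) / observed
    calls`` with the summary the mean over permutations (default; at a
    target of 0 this calls a gene only when no permuted configuration
    produces a false call), the median, or the 90th percentile, and
    pi0 capped at 1; delta is the smallest candidate meeting the target.
    """
    X, y, genes = _coerce(X, y)
    m, n = X.shape
    n2 = int(y.sum())
    if n2 == 0 or n2 == n:
        raise ValueError("labels define a single group; no permutation variation")
    if n_permutations < 100 and comb(n, n2, exact=True) > n_permutations:
        raise ValueError("n_permutations must be >= 100 (or exhaustive)")

    if s0 is None:
        s0 = estimate_s0(X, y)
        if s0 == 0.0:
            # guard for exactly-zero spread genes under permutation
            s0 = float(np.percentile(_group_stats(X, y)[1], 5))
    d = compute_d_statistics(X, y, s0)

    rng = np.random.default_rng(seed)
    B = _permutation_matrix(n, n2, n_permutations, rng)
    Dperm = _permuted_d(X, B, s0)  # (m, P)
    P = Dperm.shape[1]
    Dperm_sorted = np.sort(Dperm, axis=0)
    expected = Dperm_sorted.mean(axis=1)  # expected order statistics

    order = np.argsort(d, kind="mergesort")
    d_sorted = d[order]
    diff = d_sorted - expected

    # pi0: fraction of observed d inside the permuted interquartile range
    q25, q75 = np.percentile(Dperm, [25, 75])
    pi0 = min(1.0, ((d >= q25) & (d <= q75)).sum() / (0.5 * m))

    if fdr_summary == "mean":
        summarize = np.mean
    elif fdr_summary == "median":
        summarize = np.median
    elif fdr_summary == "q90":
        summarize = lambda f: np.percentile(f, 90)  # noqa: E731
    else:
        raise ValueError("fdr_summary must be 'mean', 'median' or 'q90'")

    def fdr_at(delta: float) -> tuple[float, np.ndarray, np.ndarray]:
        up = diff >= delta
        down = -diff >= delta
        n_called = int(up.sum() + down.sum())
        if n_called == 0:
            return 0.0, up, down
        cut_up = d_sorted[up].min() if up.any() else np.inf
        cut_low = d_sorted[down].max() if down.any() else -np.inf
        false_up = (Dperm >= cut_up).sum(axis=0) if np.isfinite(cut_up) else 0
        false_low = (Dperm <= cut_low).sum(axis=0) if np.isfinite(cut_low) else 0
        false = np.asarray(false_up) + np.asarray(false_low)
        return pi0 * float(summarize(false)) / n_called, up, down

    candidates = np.unique(np.concatenate([[0.0], np.abs(diff)]))
    delta = None
    for cand in candidates:
        fdr, up, down = fdr_at(cand)
        if fdr <= target_fdr:
            delta = float(cand)
            break
    if delta is None:  # no candidate met the target: call nothing
        delta = float(np.abs(diff).max()) + 1e-9
        fdr, up, down = fdr_at(delta)

    sorted_genes = [genes[i] for i in order]
    up_genes = [g for g, f, val in zip(sorted_genes, up, d_sorted) if f and val > 0]
    down_genes = [g for g, f, val in zip(sorted_genes, down, d_sorted) if f and val < 0]

    return SAMResult(
        genes=genes,
        d=d,
        s0=float(s0),
        delta=delta,
        significant_up=up_genes,
        significant_down=down_genes,
        estimated_fdr=float(fdr),
        n_permutations=P,
        seed=seed,
        expected_d=expected,
    )


class SAMSelector(BaseEstimator):
    """SAM differential-expression gene selector, scikit-learn style.

    Parameters mirror :func:`sam_significant_genes`.  ``fit(X, y)`` takes
    samples in rows and genes in columns (the sklearn convention) and a
    binary label vector; ``get_support()`` returns the boolean gene mask of
    significant calls, and ``transform`` subsets columns to them.

    Attributes (after fit): ``d_``, ``s0_``, ``delta_``, ``support_``,
    ``support_up_``, ``support_down_``, ``estimated_fdr_``, ``result_``.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        target_fdr: float = 0.0,
        seed: int = 0,
        s0: float | None = None,
        fdr_summary: str = "mean",
    ):
        self.n_permutations = n_permutations
        self.target_fdr = target_fdr
        self.seed = seed
        self.s0 = s0
        self.fdr_summary = fdr_summary

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.dtype != bool:
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError("y must be binary")
            y = y == classes[1]
        res = sam_significant_genes(
            X.T,
            y,
            n_permutations=self.n_permutations,
            target_fdr=self.target_fdr,
            seed=self.seed,
            s0=self.s0,
            fdr_summary=self.fdr_summary,
        )
        self.result_ = res
        self.d_ = res.d
        self.s0_ = res.s0
        self.delta_ = res.delta
        self.estimated_fdr_ = res.estimated_fdr
        idx = {g: i for i, g in enumerate(res.genes)}
        self.support_up_ = np.zeros(len(res.genes), dtype=bool)
        self.support_down_ = np.zeros(len(res.genes), dtype=bool)
        for g in res.significant_up:
            self.support_up_[idx[g]] = True
        for g in res.significant_down:
            self.support_down_[idx[g]] = True
        self.support_ = self.support_up_ | self.support_down_
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        return np.asarray(X)[:, self.support_]
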