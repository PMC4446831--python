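"""Quality-Threshold clustering under jackknife-correlation similarity.

The similarity between two gene profiles is the *jackknife correlation*:
the minimum Pearson correlation over all leave-one-sample-out deletions,
which guards cluster membership against single-sample outliers.  The QT
scheme grows a candidate cluster from every gene as seed — greedily adding
the gene that keeps the cluster's minimum pairwise similarity highest —
emits the largest candidate whose minimum pairwise similarity stays at or
above the cutoff, removes its members, and repeats until the largest
candidate falls below the minimum size (defaults: cutoff 0.4, size 15).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .io import ExpressionMatrix

__all__ = [
    "QTCluster",
    "QTClustering",
    "jackknife_correlation",
    "jackknife_correlation_matrix",
    "qt_cluster",
]


@dataclass
class QTCluster:
    members: list[str]
    seed_gene: str
    min_pairwise_similarity: float

    def __len__(self) -> int:
        return len(self.members)


def jackknife_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum leave-one-out Pearson correlation between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n or n < 4:
        raise ValueError("vectors must share length >= 4")
    worst = np.inf
    for j in range(n):
        keep = np.ones(n, dtype=bool)
        keep[j] = False
        xs, ys = x[keep], y[keep]
        if xs.std() == 0 or ys.std() == 0:
            raise ValueError(
                f"constant vector after deleting sample {j}; "
                "filter zero-variance genes first"
            )
        r = np.corrcoef(xs, ys)[0, 1]
        worst = min(worst, r)
    return float(worst)


def jackknife_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise jackknife correlations of the rows of X (genes x samples)."""
    X = np.asarray(X, dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValueError("need >= 4 samples")
    stds_del = np.empty((n_genes, n_samples))
    for j in range(n_samples):
        keep = np.ones(n_samples, dtype=bool)
        keep[j] = False
        stds_del[:, j] = X[:, keep].std(axis=1)
    if np.any(stds_del == 0):
        bad = np.where((stds_del == 0).any(axis=1))[0]
        raise ValueError(f"genes constant after a deletion: rows {bad.tolist()[:5]}")
    J = np.full((n_genes, n_genes), np.inf)
    for j in range(n_samples):
        keep = np.ones(n_samples, dtype=bool)
        keep[j] = False
        C = np.corrcoef(X[:, keep])
        np.minimum(J, C, out=J)
    J = np.minimum(J, J.T)  # corrcoef is symmetric only to rounding
    np.fill_diagonal(J, 1.0)
    return J


def _grow_cluster(
    J: np.ndarray, seed: int, alive: np.ndarray, cutoff: float
) -> tuple[list[int], float]:
    """Greedy growth from one seed; returns member indices and final min-sim."""
    members = [seed]
    in_cluster = np.zeros(J.shape[0], dtype=bool)
    in_cluster[seed] = True
    minsim_to = J[seed].copy()  # min similarity of each gene to members
    cluster_min = 1.0
    while True:
        eligible = alive & ~in_cluster
        if not eligible.any():
            break
        resulting = np.minimum(cluster_min, minsim_to)
        resulting[~eligible] = -np.inf
        best = int(np.argmax(resulting))  # argmax takes smallest index on ties
        if resulting[best] < cutoff:
            break
        cluster_min = float(resulting[best])
        members.append(best)
        in_cluster[best] = True
        np.minimum(minsim_to, J[best], out=minsim_to)
    return members, cluster_min


class QTClustering(BaseEstimator, ClusterMixin):
    """QT clustering of the rows of X, scikit-learn style.

    Parameters
    ----------
    similarity_cutoff : float, default 0.4
        Floor on the minimum pairwise jackknife correlation within a
        cluster.  With ``cutoff_as="diameter"`` the value is instead a
        ceiling on the cluster diameter 1 - r (0.6 is equivalent).
    min_size : int, default 15
        Smallest cluster that may be emitted; must be >= 2.
    standardize : bool, default True
        Row-standardize profiles before clustering (a Pearson no-op,
        kept for numerical hygiene).
    cutoff_as : {"similarity", "diameter"}

    Attributes (after fit): ``clusters_`` (list of :class:`QTCluster` over
    row indices as strings, or gene ids via :func:`qt_cluster`), and
    ``labels_`` (cluster index per row, -1 for unclustered).
    """

    def __init__(
        self,
        similarity_cutoff: float = 0.4,
        min_size: int = 15,
        standardize: bool = True,
        cutoff_as: str = "similarity",
    ):
        self.similarity_cutoff = similarity_cutoff
        self.min_size = min_size
        self.standardize = standardize
        self.cutoff_as = cutoff_as

    def _effective_cutoff(self) -> float:
        if self.cutoff_as == "similarity":
            return self.similarity_cutoff
        if self.cutoff_as == "diameter":
            return 1.0 - self.similarity_cutoff
        raise ValueError("cutoff_as must be 'similarity' or 'diameter'")

    def fit(self, X, y=None):
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        cutoff = self._effective_cutoff()
        X = np.asarray(X, dtype=float)
        if self.standardize:
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        J = jackknife_correlation_matrix(X)

        alive = np.ones(X.shape[0], dtype=bool)
        clusters: list[tuple[list[int], int, float]] = []
        while alive.sum() >= self.min_size:
            best_members: list[int] | None = None
            best_seed = -1
            best_min = -np.inf
            for seed in np.where(alive)[0]:
                members, cmin = _grow_cluster(J, int(seed), alive, cutoff)
                if best_members is None or len(members) > len(best_members):
                    best_members, best_seed, best_min = members, int(seed), cmin
            if best_members is None or len(best_members) < self.min_size:
                break
            clusters.append((best_members, best_seed, best_min))
            alive[best_members] = False

        self.labels_ = np.full(X.shape[0], -1, dtype=int)
        self.clusters_ = []
        for k, (members, seed, cmin) in enumerate(clusters):
            self.labels_[members] = k
            self.clusters_.append(
                QTCluster(
                    members=[str(i) for i in members],
                    seed_gene=str(seed),
                    min_pairwise_similarity=cmin,
                )
            )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def qt_cluster(
    expr: ExpressionMatrix | np.ndarray,
    similarity_cutoff: float = 0.4,
    min_size: int = 15,
    gene_ids: list[str] | None = None,
    cutoff_as: str = "similarity",
) -> list[QTCluster]:
    """Cluster genes of an expression matrix; thin wrapper over the estimator.

    Genes whose profile is constant after any single-sample deletion are
    dropped with a warning (their jackknife correlation is undefined).
    """
    if isinstance(expr, ExpressionMatrix):
        X = expr.values.values.astype(float)
        gene_ids = expr.genes
    else:
        X = np.asarray(expr, dtype=float)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(X.shape[0])]

    n = X.shape[1]
    ok = np.ones(X.shape[0], dtype=bool)
    for j in range(n):
        keep = np.ones(n, dtype=bool)
        keep[j] = False
        ok &= X[:, keep].std(axis=1) > 0
    if not ok.all():
        dropped = [gene_ids[i] for i in np.where(~ok)[0]]
        warnings.warn(f"dropped {len(dropped)} degenerate-profile genes: {dropped[:5]}")
    X = X[ok]
    kept_ids = [g for g, k in zip(gene_ids, ok) if k]
    if len(kept_ids) < min_size:
        return []

    est = QTClustering(
        similarity_cutoff=similarity_cutoff, min_size=min_size, cutoff_as=cutoff_as
    ).fit(X)
    out = []
    for c in est.clusters_:
        out.append(
            QTCluster(
                members=[kept_ids[int(i)] for i in c.members],
                seed_gene=kept_ids[int(c.seed_gene)],
                min_pairwise_similarity=c.min_pairwise_similarity,
            )
        )
    return out
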