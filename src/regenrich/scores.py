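"""Per-tumor regulatory-program scores.

The HOX switch score contrasts anterior HOXA/HOXB against posterior HOXA
expression: each gene row is z-standardized across samples and the score
is mean(anterior z) - mean(posterior z), so anterior-expressing
(differentiated, Urobasal-A-like) tumors score high and posterior-only
tumors score low.  Marker log-ratios (e.g. FABP4/5 over CRABP2) summarise
competing retinoid-handling programs per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix

__all__ = [
    "ANTERIOR_HOX_DEFAULT",
    "POSTERIOR_HOX_DEFAULT",
    "HoxScore",
    "HoxScorer",
    "compute_hox_score",
    "compute_marker_ratio",
]

# anterior: HOXA1-7 plus HOXB2-8; posterior: HOXA9-13 (HOXA8 and HOXB9+
# excluded by default)
ANTERIOR_HOX_DEFAULT = [f"HOXA{i}" for i in range(1, 8)] + [
    f"HOXB{i}" for i in range(2, 9)
]
POSTERIOR_HOX_DEFAULT = [f"HOXA{i}" for i in range(9, 14)]


@dataclass
class HoxScore:
    sample_id: str
    score: float
    anterior_genes_used: list[str]
    posterior_genes_used: list[str]


class HoxScorer(BaseEstimator, TransformerMixin):
    """Anterior-vs-posterior HOX balance score as a sklearn transformer.

    ``fit(X)`` learns per-gene means/SDs on X (samples x genes, column
    names supplied via ``gene_ids``); ``transform`` returns one score per
    sample: mean anterior z minus mean posterior z.  Zero-variance gene
    columns are dropped with a warning.
    """

    def __init__(
        self,
        anterior: list[str] | None = None,
        posterior: list[str] | None = None,
        gene_ids: list[str] | None = None,
    ):
        self.anterior = anterior
        self.posterior = posterior
        self.gene_ids = gene_ids

    def _resolve(self, n_cols: int):
        genes = self.gene_ids
        if genes is None:
            genes = [str(i) for i in range(n_cols)]
        anterior = self.anterior if self.anterior is not None else ANTERIOR_HOX_DEFAULT
        posterior = (
            self.posterior if self.posterior is not None else POSTERIOR_HOX_DEFAULT
        )
        index = {g: i for i, g in enumerate(genes)}
        a_idx = [index[g] for g in anterior if g in index]
        p_idx = [index[g] for g in posterior if g in index]
        return genes, anterior, posterior, a_idx, p_idx

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        genes, anterior, posterior, a_idx, p_idx = self._resolve(X.shape[1])
        if not a_idx or not p_idx:
            raise ValueError(
                f"no anterior or posterior genes found; defaults are "
                f"anterior={anterior}, posterior={posterior}"
            )
        use = np.array(a_idx + p_idx)
        mu = X[:, use].mean(axis=0)
        sd = X[:, use].std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [genes[use[i]] for i in np.where(~keep)[0]]
            warnings.warn(f"dropped zero-variance genes from HOX score: {dropped}")
        n_a = len(a_idx)
        a_keep = keep[:n_a]
        p_keep = keep[n_a:]
        if not a_keep.any() or not p_keep.any():
            raise ValueError("all anterior or all posterior genes are zero-variance")
        self.anterior_genes_ = [genes[i] for i, k in zip(a_idx, a_keep) if k]
        self.posterior_genes_ = [genes[i] for i, k in zip(p_idx, p_keep) if k]
        self.a_idx_ = np.array([i for i, k in zip(a_idx, a_keep) if k])
        self.p_idx_ = np.array([i for i, k in zip(p_idx, p_keep) if k])
        self.mu_a_, self.sd_a_ = (
            X[:, self.a_idx_].mean(axis=0),
            X[:, self.a_idx_].std(axis=0),
        )
        self.mu_p_, self.sd_p_ = (
            X[:, self.p_idx_].mean(axis=0),
            X[:, self.p_idx_].std(axis=0),
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        za = (X[:, self.a_idx_] - self.mu_a_) / self.sd_a_
        zp = (X[:, self.p_idx_] - self.mu_p_) / self.sd_p_
        return za.mean(axis=1) - zp.mean(axis=1)


def compute_hox_score(
    expr: ExpressionMatrix,
    anterior: list[str] | None = None,
    posterior: list[str] | None = None,
) -> list[HoxScore]:
    """Per-sample HOX switch score (mean anterior z minus mean posterior z)."""
    scorer = HoxScorer(anterior=anterior, posterior=posterior, gene_ids=expr.genes)
    X = expr.values.values.T  # samples x genes
    scores = scorer.fit(X).transform(X)
    return [
        HoxScore(
            sample_id=s,
            score=float(v),
            anterior_genes_used=scorer.anterior_genes_,
            posterior_genes_used=scorer.posterior_genes_,
        )
        for s, v in zip(expr.samples, scores)
    ]


def compute_marker_ratio(
    expr: ExpressionMatrix, numerator: list[str], denominator: list[str]
) -> pd.Series:
    """Per-sample log-ratio: mean log-expression of numerator minus denominator.

    Expression is assumed log-scale, so the difference is the log of the
    expression ratio; exponentiate to report the ratio itself.
    """
    for name, genes in (("numerator", numerator), ("denominator", denominator)):
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise ValueError(f"{name} genes missing from matrix: {missing}")
    num = expr.values.loc[numerator].mean(axis=0)
    den = expr.values.loc[denominator].mean(axis=0)
    out = num - den
    out.name = "log_ratio"
    return out
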