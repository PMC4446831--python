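"""Strand-aware promoter windows and the peak-to-promoter binding matrix.

Promoters are fixed windows around each gene's TSS (default -5000/+1000 bp,
mirrored on the minus strand).  Mapping every factor's peaks onto the
windows yields the :class:`BindingMatrix` that all enrichment statistics
consume: per (gene, factor), a bound flag and a peak count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneAnnotation, PeakSet

__all__ = [
    "PromoterSet",
    "BindingMatrix",
    "build_promoter_windows",
    "map_peaks_to_promoters",
    "count_cobound",
]


@dataclass
class PromoterSet:
    """One promoter window per gene, 0-based half-open.

    ``table`` columns: gene_id, chrom, start, end, strand.  ``upstream`` /
    ``downstream`` record the window parameters used (bp from the TSS).
    """

    table: pd.DataFrame
    upstream: int
    downstream: int

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def to_bed6(self, path) -> None:
        out = self.table.copy()
        out["score"] = 0
        out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class BindingMatrix:
    """genes x factors peak counts; bound flag is count > 0."""

    peak_count: pd.DataFrame  # index gene_id, columns factor, int

    @property
    def bound(self) -> pd.DataFrame:
        return self.peak_count > 0

    @property
    def genes(self) -> list[str]:
        return self.peak_count.index.tolist()

    @property
    def factors(self) -> list[str]:
        return self.peak_count.columns.tolist()

    def to_tsv(self, path) -> None:
        self.peak_count.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "BindingMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(peak_count=df.astype(int))


def build_promoter_windows(
    annotation: GeneAnnotation, upstream: int = 5000, downstream: int = 1000
) -> PromoterSet:
    """Build the per-gene promoter window around the TSS.

    A ``+`` strand gene with TSS t gets [t - upstream, t + downstream); a
    ``-`` strand gene gets the mirror [t - downstream + 1, t + upstream + 1),
    so window length is upstream + downstream on both strands.  Windows are
    clamped at 0 and at the chromosome end when sizes are known.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    t = annotation.table
    plus = t["strand"].values == "+"
    tss = t["tss"].values.astype(np.int64)
    start = np.where(plus, tss - upstream, tss - downstream + 1)
    end = np.where(plus, tss + downstream, tss + upstream + 1)
    start = np.maximum(start, 0)
    if annotation.chrom_sizes:
        sizes = t["chrom"].map(annotation.chrom_sizes).values
        known = ~pd.isna(sizes)
        end = end.astype(np.int64)
        end[known] = np.minimum(end[known], sizes[known].astype(np.int64))
    table = pd.DataFrame(
        {
            "gene_id": t["gene_id"].values,
            "chrom": t["chrom"].values,
            "start": start,
            "end": np.maximum(end, start),
            "strand": t["strand"].values,
        }
    )
    return PromoterSet(table=table, upstream=upstream, downstream=downstream)


def map_peaks_to_promoters(
    promoters: PromoterSet,
    peaksets: list[PeakSet],
    min_overlap: int = 1,
    combine: str = "add",
) -> BindingMatrix:
    """Count, per gene and factor, the peaks overlapping the gene's promoter.

    A peak counts toward every window it overlaps by at least ``min_overlap``
    bp.  Multiple peak sets for one factor combine by count addition
    (``combine="add"``) or by OR on the bound flag (``combine="or"``, counts
    capped at 1 per peakset union semantics).
    """
    if len(promoters) == 0:
        raise ValueError("empty PromoterSet")
    if combine not in ("add", "or"):
        raise ValueError("combine must be 'add' or 'or'")

    trees: dict[str, IntervalTree] = {}
    gene_ids = promoters.table["gene_id"].values
    for i, row in enumerate(promoters.table.itertuples(index=False)):
        if row.end - row.start <= 0:
            continue  # zero-width windows bind nothing
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)

    factors = list(dict.fromkeys(ps.factor for ps in peaksets))
    counts = np.zeros((len(promoters), len(factors)), dtype=np.int64)
    f_index = {f: j for j, f in enumerate(factors)}

    for ps in peaksets:
        j = f_index[ps.factor]
        per_set = np.zeros(len(promoters), dtype=np.int64)
        for chrom, start, end in ps.intervals:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                if min(end, iv.end) - max(start, iv.begin) >= min_overlap:
                    per_set[iv.data] += 1
        if combine == "add":
            counts[:, j] += per_set
        else:
            counts[:, j] = np.maximum(counts[:, j], (per_set > 0).astype(np.int64))

    return BindingMatrix(
        peak_count=pd.DataFrame(counts, index=gene_ids, columns=factors)
    )


def count_cobound(
    binding: BindingMatrix,
    query: list[str],
    factors: list[str] | None = None,
    k: int = 2,
) -> tuple[int, float]:
    """Count query genes bound by at least ``k`` of the given factors.

    Returns (count, fraction of the query).  This is the "binding of at
    least two of these factors in a majority of promoters" style summary.
    """
    if factors is None:
        factors = binding.factors
    if not 1 <= k <= len(factors):
        raise ValueError(f"k must be in [1, {len(factors)}]")
    missing = [g for g in query if g not in binding.peak_count.index]
    if missing:
        raise ValueError(f"query genes absent from binding matrix: {missing}")
    sub = binding.bound.loc[query, factors]
    n_bound_factors = sub.sum(axis=1)
    count = int((n_bound_factors >= k).sum())
    return count, count / len(query)
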