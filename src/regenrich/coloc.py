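"""Spatial colocalization profiles of factor binding around an anchor factor.

For every anchor-factor peak falling in a query gene's promoter, offsets to
all other-factor peak midpoints within a +/- window are histogrammed,
producing the metaplot that reveals spatially clustered binding of
cooperating factors (e.g. RXRA/PPARG/FOXA1/GATA3 at signature promoters).
Peak position is the integer-floor interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import PeakSet
from .promoters import PromoterSet

__all__ = ["ColocProfile", "colocalization_profile"]


@dataclass
class ColocProfile:
    anchor_factor: str
    other_factor: str
    window_bp: int
    bin_width_bp: int
    bin_edges: np.ndarray  # len n_bins + 1, covering [-window, +window]
    counts: np.ndarray  # per-bin int
    n_anchor_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1].astype(int),
                "bin_right": self.bin_edges[1:].astype(int),
                "count": self.counts.astype(int),
            }
        )


def colocalization_profile(
    anchor: PeakSet,
    other: PeakSet,
    promoters: PromoterSet,
    query: list[str],
    window_bp: int = 1000,
    bin_width_bp: int = 50,
) -> ColocProfile:
    """Histogram of other-factor peak offsets around anchor peaks in query promoters.

    Anchor events are anchor peaks overlapping a query gene's promoter
    window (an anchor peak shared by several query promoters counts once
    per promoter it overlaps).  For each event, offsets = other-peak
    midpoint - anchor-peak midpoint for all other peaks on the same
    chromosome with |offset| <= window_bp.
    """
    if window_bp <= 0 or window_bp % bin_width_bp != 0:
        raise ValueError("window_bp must be positive and divisible by bin_width_bp")
    known = set(promoters.gene_ids)
    missing = [g for g in query if g not in known]
    if missing:
        raise ValueError(f"query genes without promoters: {missing[:10]}")

    qset = set(query)
    trees: dict[str, IntervalTree] = {}
    for row in promoters.table.itertuples(index=False):
        if row.gene_id in qset and row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)

    other_pos: dict[str, np.ndarray] = {}
    for chrom, grp in other.midpoints().groupby("chrom"):
        other_pos[chrom] = np.sort(grp["pos"].values.astype(np.int64))

    edges = np.arange(-window_bp, window_bp + bin_width_bp, bin_width_bp)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    n_events = 0
    for chrom, start, end in anchor.intervals:
        tree = trees.get(chrom)
        if tree is None:
            continue
        n_hits = len(tree.overlap(start, end))
        if n_hits == 0:
            continue
        n_events += n_hits
        mid = (start + end) // 2
        pos = other_pos.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, mid - window_bp, side="left")
        hi = np.searchsorted(pos, mid + window_bp, side="right")
        offs = pos[lo:hi] - mid
        if offs.size:
            h, _ = np.histogram(offs, bins=edges)
            counts += h * n_hits
    return ColocProfile(
        anchor_factor=anchor.factor,
        other_factor=other.factor,
        window_bp=window_bp,
        bin_width_bp=bin_width_bp,
        bin_edges=edges,
        counts=counts,
        n_anchor_events=n_events,
    )
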