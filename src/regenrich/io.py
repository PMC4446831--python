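"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory domain types defined here:
:class:`GeneAnnotation`, :class:`PeakSet`, :class:`ExpressionMatrix` and
:class:`GeneSetCollection`.  Coordinates are 0-based half-open throughout
(BED convention); an annotation loader flag converts 1-based dialects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "PeakSet",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_peaks",
    "write_peaks",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
]


@dataclass
class GeneAnnotation:
    """Per-gene TSS universe after longest-transcript selection.

    ``table`` has one row per gene with columns ``gene_id``, ``chrom``,
    ``strand`` (``+``/``-``), ``tss`` (0-based) and ``transcript_length``.
    ``chrom_sizes`` maps chromosome name to length when known.
    """

    table: pd.DataFrame
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            dups = t.loc[t["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_ids after selection: {dups[:5]}")
        bad = ~t["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {t.loc[bad, 'strand'].unique()}")
        if (t["tss"] < 0).any():
            raise ValueError("negative TSS positions")
        if self.chrom_sizes is not None:
            for _, row in t.iterrows():
                size = self.chrom_sizes.get(row["chrom"])
                if size is not None and row["tss"] >= size:
                    raise ValueError(
                        f"gene {row['gene_id']}: tss {row['tss']} beyond "
                        f"{row['chrom']} length {size}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakSet:
    """ChIP-Seq peak calls for one factor: 0-based half-open intervals."""

    factor: str
    intervals: list[tuple[str, int, int]]
    cell_context: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(
                    f"degenerate interval ({chrom}, {start}, {end}) for {self.factor}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def midpoints(self) -> pd.DataFrame:
        """Integer-floor interval midpoints, one row per peak."""
        rows = [(c, (s + e) // 2) for c, s, e in self.intervals]
        return pd.DataFrame(rows, columns=["chrom", "pos"])


@dataclass
class ExpressionMatrix:
    """Log-scale genes x samples expression with per-sample group labels."""

    values: pd.DataFrame  # index gene_id, columns sample_id
    sample_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene_ids in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        missing = [s for s in self.values.columns if s not in self.sample_labels]
        if missing:
            raise ValueError(f"samples missing from labels: {missing}")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.sample_labels[s] == group for s in self.samples])


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT-style), order-preserving, duplicate-free."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {name}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# annotation


def read_gene_annotation(
    path,
    chrom_sizes_path=None,
    one_based: bool = False,
) -> GeneAnnotation:
    """Load a refFlat-like TSV and keep the longest transcript per gene.

    Expected columns: gene_id, chrom, strand, txStart, txEnd (0-based
    half-open span; ``one_based=True`` converts a 1-based inclusive
    dialect).  TSS is txStart on ``+`` and txEnd-1 on ``-``.  Ties on
    length break by lexicographically smallest (chrom, txStart).
    """
    rows = []
    seen_exact: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {lineno}: expected 5 columns, got {len(parts)}")
            gene_id, chrom, strand, s, e = parts[:5]
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: malformed strand {strand!r}")
            start, end = int(s), int(e)
            if one_based:
                start -= 1
            if start >= end:
                raise ValueError(f"line {lineno}: empty transcript span {start}..{end}")
            key = (gene_id, chrom, strand, start, end)
            if key in seen_exact:
                warnings.warn(f"line {lineno}: duplicate row for {gene_id} collapsed")
                continue
            seen_exact.add(key)
            rows.append(key)

    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "txStart", "txEnd"])
    df["transcript_length"] = df["txEnd"] - df["txStart"]
    # longest transcript wins; ties -> smallest (chrom, txStart)
    df = df.sort_values(
        ["gene_id", "transcript_length", "chrom", "txStart"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("gene_id", keep="first")
    df["tss"] = np.where(df["strand"] == "+", df["txStart"], df["txEnd"] - 1)
    table = df[["gene_id", "chrom", "strand", "tss", "transcript_length"]].reset_index(
        drop=True
    )

    sizes = None
    if chrom_sizes_path is not None:
        sizes_df = pd.read_csv(
            chrom_sizes_path, sep="\t", header=None, names=["chrom", "size"]
        )
        sizes = dict(zip(sizes_df["chrom"], sizes_df["size"]))
    return GeneAnnotation(table=table, chrom_sizes=sizes)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    """Write a refFlat-like TSV reconstructing a 1-bp-resolved span.

    Note the span is synthesized from tss/length; round-tripping preserves
    gene_id, chrom, strand, tss and transcript_length.
    """
    t = ann.table.copy()
    tx_start = np.where(
        t["strand"] == "+", t["tss"], t["tss"] - t["transcript_length"] + 1
    )
    tx_end = tx_start + t["transcript_length"]
    out = pd.DataFrame(
        {
            "gene_id": t["gene_id"],
            "chrom": t["chrom"],
            "strand": t["strand"],
            "txStart": tx_start,
            "txEnd": tx_end,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path, factor: str, cell_context: str = "") -> PeakSet:
    """Load a BED3+ file; columns beyond the third are ignored."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    return PeakSet(factor=factor, intervals=intervals, cell_context=cell_context)


def write_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path,
    labels_path,
    annotation: GeneAnnotation | None = None,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a TSV expression matrix plus a two-column sample->group labels TSV.

    When ``annotation`` is given, rows are restricted to its gene universe
    (the RefSeq-only rule).  Duplicate gene rows collapse to the row with
    the largest interquartile range.  Missing values are rejected unless
    ``impute_missing``, which fills per-gene medians.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    non_numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = non_numeric.isna() & df.notna()
    if bad.any().any():
        g, s = next(zip(*np.where(bad.values)))
        raise ValueError(
            f"non-numeric cell at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    df = non_numeric

    labels_df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample_id", "group"], dtype=str
    )
    # tolerate a header row
    if labels_df.iloc[0, 0] in ("sample_id", "sample"):
        labels_df = labels_df.iloc[1:]
    labels = dict(zip(labels_df["sample_id"], labels_df["group"]))
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing}")

    if annotation is not None:
        keep = df.index.isin(set(annotation.gene_ids))
        df = df.loc[keep]

    if df.index.duplicated().any():
        iqr = df.quantile(0.75, axis=1) - df.quantile(0.25, axis=1)
        order = np.lexsort((np.arange(len(df)), -iqr.values))
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]

    if df.isna().any().any():
        if not impute_missing:
            raise ValueError(
                "missing values present; pass impute_missing=True for per-gene medians"
            )
        df = df.T.fillna(df.median(axis=1)).T

    labels = {s: labels[s] for s in df.columns}
    return ExpressionMatrix(values=df, sample_labels=labels)


def write_expression(expr: ExpressionMatrix, path, labels_path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    with open(labels_path, "w") as fh:
        for s in expr.samples:
            fh.write(f"{s}\t{expr.sample_labels[s]}\n")


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(path) -> GeneSetCollection:
    """Load a GMT file (set_name, description, gene ids; tab-separated)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: GMT needs >=3 fields")
            name, d, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"line {lineno}: empty gene list for set {name!r}")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                warnings.warn(f"line {lineno}: duplicate genes in {name!r} removed")
            sets[name] = uniq
            desc[name] = d
    return GeneSetCollection(sets=sets, description=desc)


def write_gene_sets(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            d = gsc.description.get(name, "")
            fh.write("\t".join([name, d, *genes]) + "\n")
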