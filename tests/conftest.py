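import numpy as np
import pandas as pd
import pytest

from regenrich.io import ExpressionMatrix, GeneAnnotation, PeakSet
from regenrich.promoters import BindingMatrix


@pytest.fixture
def tiny_annotation() -> GeneAnnotation:
    table = pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC", "GD"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+", "-"],
            "tss": [10_000, 40_000, 3_000, 25_000],
            "transcript_length": [2000, 3000, 1500, 2500],
        }
    )
    return GeneAnnotation(table=table)


def make_binding(genes: list[str], counts: dict[str, list[int]]) -> BindingMatrix:
    return BindingMatrix(
        peak_count=pd.DataFrame(counts, index=genes).astype(int)
    )


def make_expression(
    X: np.ndarray, groups: list[str], gene_ids: list[str] | None = None
) -> ExpressionMatrix:
    genes = gene_ids or [f"g{i}" for i in range(X.shape[0])]
    samples = [f"s{j}" for j in range(X.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=samples),
        sample_labels=dict(zip(samples, groups)),
    )


def random_peaks(
    rng: np.random.Generator, factor: str, n: int, chroms=("chr1", "chr2"), span=100_000
) -> PeakSet:
    intervals = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(50, 500))
        intervals.append((chrom, start, end))
    return PeakSet(factor=factor, intervals=intervals)
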