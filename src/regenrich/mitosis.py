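"""Mitotic division-angle analysis against a random-orientation null.

Each mitotic figure carries the angle (degrees, 0-90) between its division
plane and the nearest basal lamina, and its distance from the lamina in
cell layers.  Mitoses are stratified by layer; for the basal stratum the
observed median angle is compared with medians of resampled angle sets of
equal size drawn from a null (uniform on [0, 90] by default, or resampled
from the pooled observed angles), one-sided toward 90 degrees — the
direction of basal, asymmetric-like divisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MitosisRecord",
    "AngleTestResult",
    "read_mitoses",
    "write_mitoses",
    "stratify_mitoses",
    "median_angle_test",
]


@dataclass
class MitosisRecord:
    tumor_id: str
    angle_deg: float
    layer: int
    group: str

    def __post_init__(self) -> None:
        if not 0 <= self.angle_deg <= 90:
            raise ValueError(
                f"record {self.tumor_id}: angle {self.angle_deg} outside [0, 90]"
            )
        if self.layer < 0:
            raise ValueError(f"record {self.tumor_id}: negative layer {self.layer}")


@dataclass
class AngleTestResult:
    group: str
    n: int
    observed_median: float
    null_median_mean: float
    null_median_lo: float  # 2.5th percentile
    null_median_hi: float  # 97.5th percentile
    p_high: float
    n_resamples: int
    seed: int


def read_mitoses(path) -> list[MitosisRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"tumor_id": str, "group": str})
    return [
        MitosisRecord(
            tumor_id=row.tumor_id,
            angle_deg=float(row.angle_deg),
            layer=int(row.layer),
            group=row.group,
        )
        for row in df.itertuples(index=False)
    ]


def write_mitoses(records: list[MitosisRecord], path) -> None:
    pd.DataFrame(
        [(r.tumor_id, r.angle_deg, r.layer, r.group) for r in records],
        columns=["tumor_id", "angle_deg", "layer", "group"],
    ).to_csv(path, sep="\t", index=False)


def stratify_mitoses(
    records: list[MitosisRecord], basal_max_layer: int = 0
) -> tuple[dict[str, list[float]], dict[str, dict[int, list[float]]]]:
    """Split angles by group: basal stratum and the full layer partition.

    Returns ``(basal, by_layer)`` where ``basal[group]`` lists angles of
    mitoses with layer <= basal_max_layer and ``by_layer[group][layer]``
    is the full layer-resolved partition (for the bee-swarm style plots).
    """
    if not records:
        raise ValueError("no mitosis records")
    basal: dict[str, list[float]] = {}
    by_layer: dict[str, dict[int, list[float]]] = {}
    for r in records:
        by_layer.setdefault(r.group, {}).setdefault(r.layer, []).append(r.angle_deg)
        basal.setdefault(r.group, [])
        if r.layer <= basal_max_layer:
            basal[r.group].append(r.angle_deg)
    return basal, by_layer


def median_angle_test(
    angles: list[float],
    n_resamples: int = 10_000,
    null: str = "uniform",
    pooled_angles: list[float] | None = None,
    seed: int = 0,
    group: str = "",
) -> AngleTestResult:
    """Permutation-style test of the median angle against a random null.

    Draws ``n_resamples`` sets of len(angles) values from the null —
    ``"uniform"`` on [0, 90], or ``"pooled"`` resampling (with
    replacement) from ``pooled_angles`` — and reports the one-sided
    add-one p-value for the observed median lying toward 90 degrees.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    if angles.size < 3:
        raise ValueError("need >= 3 angles")
    if np.any((angles < 0) | (angles > 90)):
        raise ValueError("angles outside [0, 90]")
    observed = float(np.median(angles))

    rng = np.random.default_rng(seed)
    n = angles.size
    if null == "uniform":
        draws = rng.uniform(0.0, 90.0, size=(n_resamples, n))
    elif null == "pooled":
        pool = np.asarray(
            pooled_angles if pooled_angles is not None else angles, dtype=float
        )
        draws = pool[rng.integers(0, pool.size, size=(n_resamples, n))]
    else:
        raise ValueError("null must be 'uniform' or 'pooled'")
    null_medians = np.median(draws, axis=1)
    p_high = (1 + int((null_medians >= observed).sum())) / (n_resamples + 1)
    lo, hi = np.percentile(null_medians, [2.5, 97.5])
    return AngleTestResult(
        group=group,
        n=int(n),
        observed_median=observed,
        null_median_mean=float(null_medians.mean()),
        null_median_lo=float(lo),
        null_median_hi=float(hi),
        p_high=float(p_high),
        n_resamples=n_resamples,
        seed=seed,
    )
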