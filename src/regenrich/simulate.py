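"""Synthetic cohorts with planted ground truth for every pipeline stage.

Generates gene annotation, per-factor peak files with planted promoter-
binding enrichment, a multi-subtype expression cohort with planted up/down
signatures, a tight co-expression cluster, an anterior/posterior HOX
gradient, and mitosis records with a planted near-90-degree basal bias —
each a pure function of its parameters and a seed.  A single integer seed
fans out to independent per-generator streams through
``numpy.random.SeedSequence`` spawn keys, so adding one generator never
perturbs another's output.

The default cohort mirrors a realistic subtype imbalance (131/21/85/29
samples across four groups) so unbalanced two-class contrasts are
exercised.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import ExpressionMatrix, GeneAnnotation, PeakSet
from .mitosis import MitosisRecord

__all__ = [
    "SyntheticTruth",
    "DEFAULT_GROUP_SIZES",
    "generate_annotation",
    "generate_peaks",
    "generate_expression",
    "generate_mitoses",
]

DEFAULT_GROUP_SIZES = {"UroA": 131, "UroB": 21, "GU": 85, "SCCL": 29}

_STREAMS = {"annotation": 0, "peaks": 1, "expression": 2, "mitoses": 3}


def _rng(seed: int, stream: str, subkey: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream], subkey))
    return np.random.default_rng(ss)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for planted structure, JSON round-trippable."""

    seed: int = 0
    planted_signature_up: list[str] = field(default_factory=list)
    planted_signature_down: list[str] = field(default_factory=list)
    signature_group: str = ""
    planted_enriched_factors: dict[str, float] = field(default_factory=dict)
    baseline_bind_rate: float = 0.0
    realized_bound_fraction: dict[str, float] = field(default_factory=dict)
    planted_cluster: list[str] = field(default_factory=list)
    hox_group_assignment: dict[str, str] = field(default_factory=dict)
    angle_bias: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        out = SyntheticTruth(seed=self.seed or other.seed)
        for f in (
            "planted_signature_up",
            "planted_signature_down",
            "planted_cluster",
        ):
            setattr(out, f, getattr(self, f) or getattr(other, f))
        out.signature_group = self.signature_group or other.signature_group
        out.planted_enriched_factors = {
            **self.planted_enriched_factors,
            **other.planted_enriched_factors,
        }
        out.baseline_bind_rate = self.baseline_bind_rate or other.baseline_bind_rate
        out.realized_bound_fraction = {
            **self.realized_bound_fraction,
            **other.realized_bound_fraction,
        }
        out.hox_group_assignment = {
            **self.hox_group_assignment,
            **other.hox_group_assignment,
        }
        out.angle_bias = {**self.angle_bias, **other.angle_bias}
        return out


def gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_annotation(
    n_genes: int,
    n_chroms: int = 4,
    gene_spacing_bp: int = 10_000,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> GeneAnnotation:
    """Lay genes on a jittered grid with 50/50 strands.

    Each gene owns a slot of ``gene_spacing_bp``; the TSS is jittered
    within the sub-range of the slot that keeps the default -5000/+1000
    promoter window inside the slot, so at spacing >= 7000 bp no two
    default windows overlap.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, "annotation")
    if gene_ids is None:
        gene_ids = [gene_name(i) for i in range(n_genes)]
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    per_chrom = int(np.ceil(n_genes / n_chroms))
    rows = []
    chrom_sizes = {}
    for i in range(n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = (i % per_chrom) * gene_spacing_bp
        if strands[i] == "+":
            lo = slot + 5000
            hi = max(lo, slot + gene_spacing_bp - 1000)
        else:
            lo = slot + 999
            hi = max(lo, slot + gene_spacing_bp - 6001)
        tss = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(1000, 4001))
        rows.append((gene_ids[i], chrom, strands[i], tss, length))
        chrom_sizes[chrom] = (per_chrom + 2) * gene_spacing_bp
    table = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "transcript_length"]
    )
    return GeneAnnotation(table=table, chrom_sizes=chrom_sizes)


def generate_peaks(
    annotation: GeneAnnotation,
    factor: str,
    baseline_rate: float,
    enriched_set: list[str] | None = None,
    enriched_rate: float | None = None,
    peaks_per_bound_promoter: int | tuple[int, int] = 1,
    peak_width: int = 200,
    upstream: int = 5000,
    downstream: int = 1000,
    seed: int = 0,
) -> tuple[PeakSet, SyntheticTruth]:
    """Plant promoter peaks at ``baseline_rate`` (``enriched_rate`` inside
    ``enriched_set``); positions uniform within each bound promoter window.
    """
    enriched_set = enriched_set or []
    enriched_rate = baseline_rate if enriched_rate is None else enriched_rate
    if not 0 <= baseline_rate <= enriched_rate <= 1:
        raise ValueError("need 0 <= baseline_rate <= enriched_rate <= 1")
    known = set(annotation.gene_ids)
    bad = [g for g in enriched_set if g not in known]
    if bad:
        raise ValueError(f"enriched genes absent from annotation: {bad[:10]}")
    rng = _rng(seed, "peaks", zlib.crc32(factor.encode()) % 2**31)
    enriched = set(enriched_set)
    intervals = []
    n_bound = 0
    for row in annotation.table.itertuples(index=False):
        rate = enriched_rate if row.gene_id in enriched else baseline_rate
        if rng.random() >= rate:
            continue
        n_bound += 1
        if isinstance(peaks_per_bound_promoter, int):
            k = peaks_per_bound_promoter
        else:
            k = int(rng.integers(peaks_per_bound_promoter[0], peaks_per_bound_promoter[1] + 1))
        if row.strand == "+":
            w_lo, w_hi = row.tss - upstream, row.tss + downstream
        else:
            w_lo, w_hi = row.tss - downstream + 1, row.tss + upstream + 1
        w_lo = max(w_lo, 0)
        for _ in range(max(k, 1)):
            mid = int(rng.integers(w_lo, w_hi))
            start = max(mid - peak_width // 2, 0)
            intervals.append((row.chrom, start, start + peak_width))
    truth = SyntheticTruth(
        seed=seed,
        planted_enriched_factors={factor: enriched_rate} if enriched_set else {},
        baseline_bind_rate=baseline_rate,
        realized_bound_fraction={factor: n_bound / len(annotation)},
    )
    return PeakSet(factor=factor, intervals=intervals), truth


def generate_expression(
    n_genes: int,
    groups: dict[str, int] | None = None,
    planted_up: list[str] | None = None,
    planted_down: list[str] | None = None,
    signature_group: str = "SCCL",
    effect_sd: float = 3.0,
    noise_sd: float = 1.0,
    cluster_config: dict | None = None,
    hox_config: dict | None = None,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-group log-expression cohort with planted structure.

    Background is N(0, noise_sd^2).  ``planted_up``/``planted_down`` genes
    shift by +/- effect_sd * noise_sd in ``signature_group``.
    ``cluster_config`` (keys: genes, loading=1.0, cluster_noise=0.3)
    replaces those genes' values by a shared per-sample latent factor plus
    independent noise (expected pairwise r = loading^2 / (loading^2 +
    cluster_noise^2)).  ``hox_config`` (keys: anterior, posterior,
    anterior_high_groups, shift=2.0) shifts anterior genes up in the
    anterior-high groups and posterior genes up elsewhere.
    """
    groups = dict(groups) if groups else dict(DEFAULT_GROUP_SIZES)
    planted_up = list(planted_up or [])
    planted_down = list(planted_down or [])
    if set(planted_up) & set(planted_down):
        raise ValueError("planted up/down lists overlap")
    if gene_ids is None:
        gene_ids = [gene_name(i) for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length mismatch")
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for g in planted_up + planted_down:
        if g not in gidx:
            raise ValueError(f"planted gene {g} not in gene universe")

    rng = _rng(seed, "expression")
    sample_ids = []
    labels = {}
    for label, n in groups.items():
        for j in range(n):
            sid = f"{label}_{j:03d}"
            sample_ids.append(sid)
            labels[sid] = label
    n_samples = len(sample_ids)
    X = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    in_group = np.array([labels[s] == signature_group for s in sample_ids])
    shift = effect_sd * noise_sd
    for g in planted_up:
        X[gidx[g], in_group] += shift
    for g in planted_down:
        X[gidx[g], in_group] -= shift

    truth = SyntheticTruth(
        seed=seed,
        planted_signature_up=planted_up,
        planted_signature_down=planted_down,
        signature_group=signature_group if (planted_up or planted_down) else "",
    )

    if cluster_config:
        genes = cluster_config["genes"]
        loading = float(cluster_config.get("loading", 1.0))
        cnoise = float(cluster_config.get("cluster_noise", 0.3))
        latent = rng.normal(0.0, 1.0, size=n_samples)
        for g in genes:
            X[gidx[g]] = loading * latent + rng.normal(0.0, cnoise, size=n_samples)
        truth.planted_cluster = list(genes)

    if hox_config:
        anterior = hox_config["anterior"]
        posterior = hox_config["posterior"]
        high_groups = set(hox_config.get("anterior_high_groups", []))
        hshift = float(hox_config.get("shift", 2.0)) * noise_sd
        a_high = np.array([labels[s] in high_groups for s in sample_ids])
        for g in anterior:
            X[gidx[g], a_high] += hshift
        for g in posterior:
            X[gidx[g], ~a_high] += hshift
        truth.hox_group_assignment = {
            s: ("anterior-high" if h else "posterior-high")
            for s, h in zip(sample_ids, a_high)
        }

    values = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=values, sample_labels=labels), truth


def generate_mitoses(
    n: int = 416,
    basal_fraction: float = 0.4,
    basal_angle_mean: float = 75.0,
    basal_angle_sd: float = 15.0,
    group: str = "UroA",
    max_layer: int = 5,
    seed: int = 0,
) -> tuple[list[MitosisRecord], SyntheticTruth]:
    """Mitosis records with a planted near-90-degree basal angle bias.

    Basal records (layer 0, a ``basal_fraction`` of the total) draw angles
    from a truncated normal on [0, 90]; non-basal records draw uniform
    angles and layers 1..max_layer with geometrically decaying weights.
    """
    if not 0 <= basal_fraction <= 1:
        raise ValueError("basal_fraction must be in [0, 1]")
    rng = _rng(seed, "mitoses")
    n_basal = int(round(n * basal_fraction))
    records = []
    if n_basal and basal_angle_sd > 0:
        a = (0.0 - basal_angle_mean) / basal_angle_sd
        b = (90.0 - basal_angle_mean) / basal_angle_sd
        basal_angles = truncnorm.rvs(
            a, b, loc=basal_angle_mean, scale=basal_angle_sd,
            size=n_basal, random_state=rng,
        )
    else:
        basal_angles = np.full(n_basal, min(max(basal_angle_mean, 0.0), 90.0))
    for i, ang in enumerate(basal_angles):
        records.append(
            MitosisRecord(
                tumor_id=f"T{i // 4:03d}", angle_deg=float(ang), layer=0, group=group
            )
        )
    n_rest = n - n_basal
    weights = 0.5 ** np.arange(1, max_layer + 1)
    weights /= weights.sum()
    layers = rng.choice(np.arange(1, max_layer + 1), size=n_rest, p=weights)
    angles = rng.uniform(0.0, 90.0, size=n_rest)
    for i in range(n_rest):
        records.append(
            MitosisRecord(
                tumor_id=f"T{(n_basal + i) // 4:03d}",
                angle_deg=float(angles[i]),
                layer=int(layers[i]),
                group=group,
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        angle_bias={
            "basal_mean_deg": basal_angle_mean,
            "basal_sd_deg": basal_angle_sd,
            "nonbasal": "uniform(0,90)",
            "basal_fraction": basal_fraction,
        },
    )
    return records, truth
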