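"""Config-driven orchestration of the full analysis.

``validate_config`` injects documented defaults (promoter window -5000/+1000,
QTC 0.4/15, 100 000 enrichment resamples, +/-1000 bp colocalization window,
10^4 angle resamples) and rejects unknown or out-of-range keys;
``run_pipeline`` loads the inputs, derives subtype signatures (SAM), runs the
enrichment and colocalization stages per factor, computes HOX scores, marker
ratios and angle tests, and writes a report directory.  Every stage is also
callable on its own (the CLI subcommands go through the same functions), and
a fixed config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import difflib
import json
import os

import numpy as np
import pandas as pd

from . import io as rio
from .coloc import colocalization_profile
from .enrichment import fisher_enrichment, resampling_enrichment
from .mitosis import median_angle_test, read_mitoses, stratify_mitoses, write_mitoses
from .promoters import BindingMatrix, build_promoter_windows, count_cobound, \
    map_peaks_to_promoters
from .qtc import qt_cluster
from .sam import sam_significant_genes
from .scores import ANTERIOR_HOX_DEFAULT, POSTERIOR_HOX_DEFAULT, compute_hox_score, \
    compute_marker_ratio
from . import simulate as sim

__all__ = ["DEFAULT_PARAMS", "validate_config", "run_pipeline", "make_fixture"]

# Defaults follow the printed analysis parameters: promoter window
# -5000/+1000 bp, QTC cutoff 0.4 and min size 15, SAM target FDR 0,
# 100 000 resampled gene lists, +/-1000 bp coloc window, 10^4 angle sets.
DEFAULT_PARAMS: dict = {
    "promoter": {"upstream": 5000, "downstream": 1000},
    "qtc": {"cutoff": 0.4, "min_size": 15, "max_genes": 200},
    "sam": {"n_permutations": 1000, "target_fdr": 0.0, "groups": None},
    "enrichment": {"n_resamples": 100_000},
    "coloc": {"window_bp": 1000, "bin_width_bp": 50, "anchor": None},
    "cobinding": {"k": 2},
    "hox": {"anterior": ANTERIOR_HOX_DEFAULT, "posterior": POSTERIOR_HOX_DEFAULT},
    "markers": {"numerator": None, "denominator": None},
    "angles": {"n_resamples": 10_000, "basal_max_layer": 0, "null": "uniform"},
}

_KNOWN_PATHS = {"annotation", "chrom_sizes", "expression", "labels", "gene_sets",
                "mitoses", "peaks"}
_TOP_KEYS = {"seed", "output_dir", "paths", "params"}


def _check_keys(given: dict, known: set[str], where: str) -> None:
    for key in given:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown key {key!r} in {where}{extra}")


def validate_config(config: dict) -> dict:
    """Validate a raw config dict, inject defaults, check ranges and paths."""
    _check_keys(config, _TOP_KEYS, "config")
    cfg = copy.deepcopy(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "regenrich_out")
    cfg.setdefault("paths", {})
    _check_keys(cfg["paths"], _KNOWN_PATHS, "paths")

    params = cfg.setdefault("params", {})
    _check_keys(params, set(DEFAULT_PARAMS), "params")
    for section, defaults in DEFAULT_PARAMS.items():
        block = params.setdefault(section, {})
        _check_keys(block, set(defaults), f"params.{section}")
        for key, val in defaults.items():
            block.setdefault(key, copy.deepcopy(val))

    p = params
    if p["promoter"]["upstream"] < 0 or p["promoter"]["downstream"] < 0:
        raise ValueError("promoter window bounds must be >= 0")
    if not -1 <= p["qtc"]["cutoff"] <= 1:
        raise ValueError("qtc.cutoff must lie in [-1, 1]")
    if p["qtc"]["min_size"] < 2:
        raise ValueError("qtc.min_size must be >= 2")
    if p["sam"]["n_permutations"] < 100:
        raise ValueError("sam.n_permutations must be >= 100")
    if not 0 <= p["sam"]["target_fdr"] <= 1:
        raise ValueError("sam.target_fdr must lie in [0, 1]")
    if p["enrichment"]["n_resamples"] < 100:
        raise ValueError("enrichment.n_resamples must be >= 100")
    if p["coloc"]["window_bp"] <= 0 or \
            p["coloc"]["window_bp"] % p["coloc"]["bin_width_bp"] != 0:
        raise ValueError("coloc.window_bp must be positive and divisible by bin width")
    if p["angles"]["n_resamples"] < 100:
        raise ValueError("angles.n_resamples must be >= 100")
    if p["angles"]["basal_max_layer"] < 0:
        raise ValueError("angles.basal_max_layer must be >= 0")
    if p["angles"]["null"] not in ("uniform", "pooled"):
        raise ValueError("angles.null must be 'uniform' or 'pooled'")
    if p["cobinding"]["k"] < 1:
        raise ValueError("cobinding.k must be >= 1")

    for key, val in cfg["paths"].items():
        if key == "peaks":
            for factor, paths in val.items():
                for path in paths if isinstance(paths, list) else [paths]:
                    if not os.path.exists(path):
                        raise ValueError(f"peaks path for {factor} missing: {path}")
        elif val is not None and not os.path.exists(val):
            raise ValueError(f"path for {key!r} missing: {val}")
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(100, zlib.crc32(stage.encode()) % 2**31))
    return int(ss.generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# stages (shared by run_pipeline and the CLI subcommands)


def stage_sam(expr, group, params, seed, out_dir):
    res = sam_significant_genes(
        expr,
        group,
        n_permutations=params["sam"]["n_permutations"],
        target_fdr=params["sam"]["target_fdr"],
        seed=_stage_seed(seed, f"sam:{group}"),
    )
    res.to_frame().to_csv(os.path.join(out_dir, f"sam_{group}.tsv"), sep="\t",
                          index=False, float_format="%.6g")
    meta = {"group": group, "s0": res.s0, "delta": res.delta,
            "estimated_fdr": res.estimated_fdr,
            "n_permutations": res.n_permutations, "seed": res.seed}
    with open(os.path.join(out_dir, f"sam_{group}_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return res


def stage_enrichment(binding, signatures, params, seed, out_dir):
    rows = []
    for sig_name, genes in signatures.items():
        if not genes:
            continue
        for factor in binding.factors:
            res = resampling_enrichment(
                binding, genes, factor,
                n_resamples=params["enrichment"]["n_resamples"],
                seed=_stage_seed(seed, f"enrich:{sig_name}:{factor}"),
            )
            row = res.summary_row()
            row["signature"] = sig_name
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df[["signature"] + [c for c in df.columns if c != "signature"]]
    df.to_csv(os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False,
              float_format="%.6g")
    return df


def stage_cobinding(binding, signatures, k, out_dir):
    rows = []
    for sig_name, genes in signatures.items():
        if not genes:
            continue
        count, frac = count_cobound(binding, genes, k=k)
        rows.append({"signature": sig_name, "k": k, "n_genes": len(genes),
                     "n_cobound": count, "fraction": frac})
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(out_dir, "cobinding.tsv"), sep="\t", index=False,
              float_format="%.6g")
    return df


def stage_coloc(peaksets, promoters, query, params, out_dir):
    anchor_name = params["coloc"]["anchor"] or peaksets[0].factor
    by_name = {ps.factor: ps for ps in peaksets}
    anchor = by_name[anchor_name]
    profiles = {}
    for ps in peaksets:
        if ps.factor == anchor_name:
            continue
        prof = colocalization_profile(
            anchor, ps, promoters, query,
            window_bp=params["coloc"]["window_bp"],
            bin_width_bp=params["coloc"]["bin_width_bp"],
        )
        prof.to_frame().to_csv(
            os.path.join(out_dir, f"coloc_{anchor_name}_{ps.factor}.tsv"),
            sep="\t", index=False)
        profiles[ps.factor] = prof
    return profiles


def stage_qtc(expr, params, out_dir):
    values = expr.values
    max_genes = params["qtc"]["max_genes"]
    if max_genes and len(values) > max_genes:
        var = values.var(axis=1)
        keep = var.sort_values(ascending=False, kind="mergesort").index[:max_genes]
        keep = [g for g in values.index if g in set(keep)]  # preserve input order
        values = values.loc[keep]
        expr = rio.ExpressionMatrix(values=values, sample_labels=expr.sample_labels)
    clusters = qt_cluster(expr, similarity_cutoff=params["qtc"]["cutoff"],
                          min_size=params["qtc"]["min_size"])
    rows = []
    for cid, c in enumerate(clusters):
        for g in c.members:
            rows.append({"cluster_id": cid, "gene": g,
                         "is_seed": g == c.seed_gene,
                         "min_pairwise_similarity": c.min_pairwise_similarity})
    pd.DataFrame(rows, columns=["cluster_id", "gene", "is_seed",
                                "min_pairwise_similarity"]).to_csv(
        os.path.join(out_dir, "qtc_clusters.tsv"), sep="\t", index=False,
        float_format="%.6g")
    return clusters


def stage_hox(expr, params, out_dir):
    scores = compute_hox_score(expr, anterior=params["hox"]["anterior"],
                               posterior=params["hox"]["posterior"])
    df = pd.DataFrame(
        {"sample_id": [s.sample_id for s in scores],
         "hox_score": [s.score for s in scores],
         "group": [expr.sample_labels[s.sample_id] for s in scores]})
    df = df.sort_values("hox_score", ascending=False, kind="mergesort")
    df.to_csv(os.path.join(out_dir, "hox_scores.tsv"), sep="\t", index=False,
              float_format="%.6g")
    return df


def stage_markers(expr, params, out_dir):
    num = params["markers"]["numerator"]
    den = params["markers"]["denominator"]
    if not num or not den:
        return None
    ratios = compute_marker_ratio(expr, num, den)
    df = pd.DataFrame({"sample_id": ratios.index, "log_ratio": ratios.values,
                       "ratio": np.exp(ratios.values)})
    df.to_csv(os.path.join(out_dir, "marker_ratios.tsv"), sep="\t", index=False,
              float_format="%.6g")
    return df


def stage_angles(records, params, seed, out_dir):
    basal, _ = stratify_mitoses(records,
                                basal_max_layer=params["angles"]["basal_max_layer"])
    pooled = [r.angle_deg for r in records]
    rows = []
    for group, angles in sorted(basal.items()):
        if len(angles) < 3:
            continue
        res = median_angle_test(
            angles, n_resamples=params["angles"]["n_resamples"],
            null=params["angles"]["null"], pooled_angles=pooled,
            seed=_stage_seed(seed, f"angles:{group}"), group=group)
        rows.append(vars(res))
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(out_dir, "angle_tests.tsv"), sep="\t", index=False,
              float_format="%.6g")
    return df


def run_pipeline(config: dict) -> str:
    """Run every configured stage; returns the report directory path."""
    cfg = validate_config(config)
    params = cfg["params"]
    seed = cfg["seed"]
    out_dir = cfg["output_dir"]
    os.makedirs(out_dir, exist_ok=True)
    paths = cfg["paths"]

    annotation = None
    if paths.get("annotation"):
        annotation = rio.read_gene_annotation(paths["annotation"],
                                              paths.get("chrom_sizes"))

    binding = None
    promoters = None
    peaksets = []
    if annotation is not None and paths.get("peaks"):
        promoters = build_promoter_windows(
            annotation, upstream=params["promoter"]["upstream"],
            downstream=params["promoter"]["downstream"])
        promoters.to_bed6(os.path.join(out_dir, "promoters.bed"))
        for factor, fpaths in paths["peaks"].items():
            for path in fpaths if isinstance(fpaths, list) else [fpaths]:
                peaksets.append(rio.read_peaks(path, factor))
        binding = map_peaks_to_promoters(promoters, peaksets)
        binding.to_tsv(os.path.join(out_dir, "binding_matrix.tsv"))

    expr = None
    signatures: dict[str, list[str]] = {}
    if paths.get("expression"):
        expr = rio.read_expression(paths["expression"], paths["labels"],
                                   annotation=annotation)
        groups = params["sam"]["groups"]
        if groups is None:
            groups = sorted(set(expr.sample_labels.values()))
        for group in groups:
            res = stage_sam(expr, group, params, seed, out_dir)
            signatures[f"{group}_up"] = res.significant_up
            signatures[f"{group}_down"] = res.significant_down

    if binding is not None and signatures:
        usable = {n: [g for g in genes if g in set(binding.genes)]
                  for n, genes in signatures.items()}
        stage_enrichment(binding, usable, params, seed, out_dir)
        stage_cobinding(binding, usable, params["cobinding"]["k"], out_dir)
        query = next((g for g in usable.values() if g), None)
        if query and len(peaksets) > 1:
            stage_coloc(peaksets, promoters, query, params, out_dir)

    if expr is not None:
        stage_qtc(expr, params, out_dir)
        try:
            stage_hox(expr, params, out_dir)
        except ValueError:
            pass  # cohort without HOX genes: stage skipped
        stage_markers(expr, params, out_dir)

    if paths.get("mitoses"):
        records = read_mitoses(paths["mitoses"])
        stage_angles(records, params, seed, out_dir)

    with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
        json.dump({"config": cfg, "signature_sizes":
                   {k: len(v) for k, v in signatures.items()}},
                  fh, indent=1, sort_keys=True)
    return out_dir


# ---------------------------------------------------------------------------
# bundled synthetic fixture


def make_fixture(out_dir: str, seed: int = 0, n_genes: int = 2000,
                 groups: dict[str, int] | None = None,
                 n_down: int = 60, n_up: int = 40, effect_sd: float = 3.0,
                 baseline_rate: float = 0.2, enriched_rate: float = 0.7,
                 n_mitoses: int = 416,
                 enrichment_resamples: int = 10_000,
                 sam_groups: list[str] | None = None) -> dict:
    """Write a complete synthetic input directory plus a ready config.

    Plants: an up/down signature in the SCCL-like group, two factors
    (RXRA, PPARG) whose promoter binding is enriched in the down
    signature against two unenriched controls, a tight 20-gene
    co-expression cluster, an anterior/posterior HOX gradient
    (anterior-high in the Uro groups), and a near-90-degree basal
    division-angle bias in the UroA-like mitoses.  Returns the config
    dict (also written as YAML) whose run exercises every stage.
    """
    import yaml

    os.makedirs(out_dir, exist_ok=True)
    groups = dict(groups) if groups else dict(sim.DEFAULT_GROUP_SIZES)

    special = (ANTERIOR_HOX_DEFAULT + POSTERIOR_HOX_DEFAULT
               + ["FABP4", "FABP5", "CRABP2"])
    gene_ids = special + [sim.gene_name(i) for i in range(n_genes - len(special))]

    annotation = sim.generate_annotation(n_genes, seed=seed, gene_ids=gene_ids)
    ann_path = os.path.join(out_dir, "annotation.tsv")
    rio.write_gene_annotation(annotation, ann_path)
    sizes_path = os.path.join(out_dir, "chrom_sizes.tsv")
    with open(sizes_path, "w") as fh:
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    background = [g for g in gene_ids if g.startswith("G")]
    planted_down = background[:n_down]
    planted_up = background[n_down:n_down + n_up]
    cluster_genes = background[n_down + n_up:n_down + n_up + 20]

    expr, truth_e = sim.generate_expression(
        n_genes, groups=groups, planted_up=planted_up, planted_down=planted_down,
        signature_group="SCCL", effect_sd=effect_sd,
        cluster_config={"genes": cluster_genes, "loading": 1.3,
                        "cluster_noise": 0.3},
        hox_config={"anterior": ANTERIOR_HOX_DEFAULT,
                    "posterior": POSTERIOR_HOX_DEFAULT,
                    "anterior_high_groups": ["UroA", "UroB"], "shift": 2.0},
        gene_ids=gene_ids, seed=seed)
    expr_path = os.path.join(out_dir, "expression.tsv")
    labels_path = os.path.join(out_dir, "labels.tsv")
    rio.write_expression(expr, expr_path, labels_path)

    peak_paths = {}
    truth = truth_e
    factor_specs = [("RXRA", enriched_rate), ("PPARG", enriched_rate),
                    ("CTRL1", None), ("CTRL2", None)]
    for factor, rate in factor_specs:
        ps, truth_p = sim.generate_peaks(
            annotation, factor, baseline_rate=baseline_rate,
            enriched_set=planted_down if rate else [],
            enriched_rate=rate, seed=seed)
        path = os.path.join(out_dir, f"peaks_{factor}.bed")
        rio.write_peaks(ps, path)
        peak_paths[factor] = [path]
        truth = truth.merge(truth_p)

    gmt_path = os.path.join(out_dir, "gene_sets.gmt")
    rio.write_gene_sets(rio.GeneSetCollection(
        sets={"PLANTED_DOWN": planted_down, "PLANTED_UP": planted_up,
              "PLANTED_CLUSTER": cluster_genes},
        description={"PLANTED_DOWN": "planted SCCL-down signature",
                     "PLANTED_UP": "planted SCCL-up signature",
                     "PLANTED_CLUSTER": "planted co-expression cluster"}),
        gmt_path)

    rec_uro, truth_m = sim.generate_mitoses(
        n=n_mitoses // 2, basal_fraction=0.5, basal_angle_mean=80.0,
        basal_angle_sd=10.0, group="UroA_lowgrade", seed=seed)
    rec_high, _ = sim.generate_mitoses(
        n=n_mitoses - n_mitoses // 2, basal_fraction=0.25,
        basal_angle_mean=45.0, basal_angle_sd=26.0, group="GU_SCCL",
        seed=seed + 1)
    mit_path = os.path.join(out_dir, "mitoses.tsv")
    write_mitoses(rec_uro + rec_high, mit_path)
    truth = truth.merge(truth_m)
    truth.seed = seed
    truth.to_json(os.path.join(out_dir, "truth.json"))

    config = {
        "seed": seed,
        "output_dir": os.path.join(out_dir, "report"),
        "paths": {"annotation": ann_path, "chrom_sizes": sizes_path,
                  "expression": expr_path, "labels": labels_path,
                  "gene_sets": gmt_path, "mitoses": mit_path,
                  "peaks": peak_paths},
        "params": {"sam": {"groups": sam_groups or ["SCCL"]},
                   "enrichment": {"n_resamples": enrichment_resamples},
                   "coloc": {"anchor": "RXRA"},
                   "markers": {"numerator": ["FABP4", "FABP5"],
                               "denominator": ["CRABP2"]}},
    }
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config
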