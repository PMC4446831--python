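# regenrich

Regulatory-genomics analysis of tumor expression subtypes: derive subtype
gene signatures, test them for transcription-factor promoter-binding
enrichment, and score the regulatory programs that distinguish
differentiated from dedifferentiated tumors.

The package grew out of the analysis style used for urothelial-carcinoma
molecular subtypes (Urobasal A/B, Genomically Unstable, SCC-like), where
subtype-specific down-regulated genes turn out to be dense in binding
sites of the differentiation factors (RXRA/PPARG, FOXA1/GATA3), anterior
versus posterior HOX expression separates differentiated from
undifferentiated tumors, and basal mitoses in low-grade tumors divide at
near-90° angles to the basal lamina.  Every stage is reusable on any
cohort in the same input formats, and a synthetic-cohort generator plants
ground truth for all of them, so the full pipeline is testable without
external downloads.

## What it computes

* **Signatures** — two-class SAM, one subtype vs the rest:
  `d_i = (x̄₂ᵢ − x̄₁ᵢ)/(sᵢ + s₀)` with permutation-estimated FDR and the
  threshold δ chosen for a target FDR (default 0: no permuted labeling may
  produce a false call past the cut); and quality-threshold clustering
  under jackknife correlation (minimum leave-one-sample-out Pearson),
  cutoff 0.4, minimum cluster size 15.
* **Binding enrichment** — per (signature, factor): a one-tailed Fisher's
  exact test `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, plus a resampling test
  against 100 000 random same-size gene lists scoring both the number of
  bound promoters and the total peak count (add-one empirical p, floor
  `1/(R+1)`); co-binding summaries (genes bound by ≥ k factors); and
  hypergeometric gene-list overlaps for GO-style sets.
* **Colocalization** — histogram of one factor's peak midpoints around an
  anchor factor's peaks within signature promoters, ±1000 bp in 50-bp bins.
* **HOX switch score** — per sample, `mean(z anterior) − mean(z posterior)`
  with anterior = HOXA1–7 ∪ HOXB2–8 and posterior = HOXA9–13; plus marker
  log-ratios (e.g. FABP4/5 vs CRABP2).
* **Division angles** — median basal division angle against medians of 10⁴
  same-size draws from a uniform(0°, 90°) orientation null, one-sided
  toward 90°.

Inputs are plain formats: refFlat-like TSV annotation (longest transcript
per gene), BED3+ peak files, TSV expression matrix + sample labels, GMT
gene sets, TSV mitosis records.  See `docs/methods.md` for the full
statistical definitions and design choices.

## Worked example

Simulate a cohort with planted truth and run every stage:

```python
from regenrich import make_fixture, run_pipeline
import pandas as pd

config = make_fixture("demo", seed=42, n_genes=1000,
                      groups={"UroA": 60, "UroB": 12, "GU": 40, "SCCL": 20},
                      enrichment_resamples=10_000)
report = run_pipeline(config)

enr = pd.read_csv(f"{report}/enrichment.tsv", sep="\t")
print(enr[enr.signature == "SCCL_down"][["factor", "n_bound_query",
      "query_size", "fisher_p", "resampling_p_bound"]].to_string(index=False))
```

```
factor  n_bound_query  query_size     fisher_p  resampling_p_bound
  RXRA             34          62 4.389340e-08            0.000100
 PPARG             43          62 8.300300e-16            0.000100
 CTRL1             11          62 5.686370e-01            0.567043
 CTRL2             14          62 3.347840e-01            0.332967
```

The SAM-derived SCCL-down signature (62 genes) is strongly enriched for
the two factors whose binding was planted at an elevated rate in those
promoters — both tests at or near their floors — while the two control
factors sit at null-level p-values.  The other report files tell the rest
of the story: the angle test puts the planted near-90° basal bias at the
resampling floor in the low-grade group only,

```
        group   n  observed_median   p_high
      GU_SCCL  52          43.8662 0.576742
UroA_lowgrade 104          78.3706 0.000100
```

and mean HOX scores separate the anterior-high Uro groups (+1.3, +1.0)
from the posterior-high GU/SCCL groups (−1.6, −1.5).

The same run is available from the shell:

```sh
regenrich simulate --out demo --seed 42
regenrich run-all --config demo/config.yaml
```

with per-stage subcommands (`sam`, `qtc`, `enrich`, `coloc`, `hoxscore`,
`angles`) that reproduce the corresponding `run-all` outputs exactly.

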