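# dimorphix

Multi-omic analysis of sex-dimorphic disease signatures, built for the
question of X-chromosome inactivation (XCI) biology in male systemic
lupus erythematosus (SLE): does a male cohort show ectopic expression of
the XIST long non-coding RNA, hypermethylation of X-linked loci, and
transcriptional silencing of X-linked genes — and how do those signals
split the cohort clinically?

The package is for computational biologists analysing case/control
cohorts with methylation, RNA-seq and protein (NPX) layers plus clinical
metadata, and for methodologists who want the underlying primitives —
the Hartigan dip test, Sheather–Jones density-trough classification,
preranked chromosome-set GSEA, empirical-Bayes factorial models — as
tested, reusable functions.

## What it computes

Every modality is fit with the 2×2 factorial model
`y = β₀ + β₁·sex + β₂·disease + β₃·(sex:disease)` (female/HC = 0), with
empirical-Bayes variance moderation: per-feature variances shrink toward
a pooled prior `(d₀, s₀²)` estimated by digamma/trigamma moment matching,
and contrasts are tested with the moderated t
`t = c'β / (s̃·SE)`, `s̃² = (d₀s₀² + d_g s²)/(d₀+d_g)`. The interaction
`β₃ = [M-SLE − M-HC] − [F-SLE − F-HC]` isolates disease responses that
differ between the sexes. Calls use Benjamini–Hochberg FDR ≤ 0.1 and
|fold change| > 1.5.

Around that core:

* **XIST bimodality** — Hartigan & Hartigan's dip statistic (the
  sup-norm distance from the ECDF to the closest unimodal CDF, computed
  by the convex-minorant/concave-majorant algorithm) with a Monte-Carlo
  uniform null; classification of males into XIST-high/low by the trough
  of a Sheather–Jones-bandwidth KDE of ΔΔCt-normalized qPCR expression,
  with an RNA-seq fallback for samples missing qPCR.
* **Chromosome-level enrichment** — preranked GSEA against chromosome
  gene sets (pseudoautosomal genes split into their own "PAR" set) and
  exact hypergeometric over-representation, for X-silencing scans across
  modalities.
* **Deconvolution benchmarking** — NNLS/OLS estimation of immune-cell
  proportions from TPM against reference profiles, scored against flow
  cytometry (mean of B-cell and NK correlations selects the pair).
* **Clinical screens** — Wilcoxon/chi-square group comparisons and
  Spearman feature–covariate screens, BH-corrected per family; a 6-gene
  type-I interferon signature score.
* **A synthetic cohort generator** that plants the full effect structure
  (bimodal male XIST with 54% in the elevated mode, male-only X
  hypermethylation, shared interferon upregulation, sparse X protein
  coverage, karyotype anomalies, flow/clinical metadata) with ground
  truth for recovery testing.

See `docs/methods.md` for the model details, generator design and known
limitations.

## Worked example

Simulate a cohort, test male XIST expression for bimodality, and
classify the males:

```python
import numpy as np
from dimorphix import CohortSpec, simulate_cohort
from dimorphix.xist_bimodality import classify_xist, dip_test, normalize_qpcr

spec = CohortSpec(n_f_sle=60, n_f_hc=20, n_m_sle=41, n_m_hc=7,
                  n_rna=800, n_promoter=400, n_gene_meth=400,
                  n_protein=300, n_protein_x=15, seed=1)
cohort = simulate_cohort(spec)
s = cohort.samples
males = s.index[(s.sex == "M") & (s.disease == "SLE")]

rel = normalize_qpcr(s["ct_xist"], s["ct_gapdh"], s["sex"], s["disease"] == "HC")
log_rel = np.log2(rel).reindex(males)

res = dip_test(log_rel.dropna().to_numpy(), n_mc=10000, seed=1)
print(f"dip D = {res.statistic:.4f}, p = {res.p_value:.4f} (n = {res.n})")

cls = classify_xist(log_rel, rnaseq=cohort.ground_truth.xist_logexpr.reindex(males))
n_high = (cls.labels == "high").sum()
print(f"XIST-high: {n_high}/{len(males)} males, threshold = {cls.threshold:.2f}, "
      f"{(cls.sources == 'rnaseq').sum()} classified from RNA-seq")
```

prints

```
dip D = 0.1077, p = 0.0007 (n = 38)
XIST-high: 23/41 males, threshold = 4.87, 3 classified from RNA-seq
```

Reading: the 38 males with qPCR depart strongly from unimodality
(D = 0.108 against a Monte-Carlo uniform null), the KDE trough at 4.87
log₂ relative-expression units splits the 41 males into 23 high / 18
low (the three lacking qPCR were classified on an independent RNA-seq
threshold), and — since this is a simulated cohort — the labels can be
checked against the generator's latent classes (100% agreement here).

The full pipeline (QC → differential analysis → classification →
chromosome scans → deconvolution → clinical screens) runs from one
config:

```sh
dimorphix run --config config/default.yaml --outdir out --seed 1
```

writing per-stage TSVs and a JSON manifest with seeds, per-filter counts
and artifact digests; a rerun with the same config is bit-identical.
Individual stages are exposed as subcommands (`dip-test`,
`classify-xist`, `de`, `gsea`, `ora`, `chrom-scan`, `deconv`, `screen`,
`correlate`).

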