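# Default pipeline configuration. Every analysis constant lives here;
# values are the package defaults and can be overridden per run.

outdir: dimorphix_out
seed: 0

# significance calls: FDR <= fdr_max AND |fold change| > fc_min
fdr_max: 0.1
fc_min: 1.5

# protein QC: assay kept iff strictly more than lod_min_frac of samples
# exceed its limit of detection; samples more than sample_exclusion_sd
# standard deviations below the cohort mean NPX are dropped
lod_min_frac: 0.75
sample_exclusion_sd: 4.0

# RNA-seq low-count filter (CPM cutoff keyed to the smallest design cell)
min_count: 10

# sex QC: flag when |X/autosome ratio - expected| > sex_qc_tol
# (expected 0.5 for XY males, 1.0 for XX females)
sex_qc_tol: 0.25

# promoter window around the TSS (bp; strand-aware, clipped at 0)
promoter_upstream: 2000
promoter_downstream: 200

# permutation / Monte-Carlo sizes (chromosome scans and dip tests)
n_perm: 1000
n_mc: 10000

# toggles
use_voom_weights: true     # precision weights for the RNA fits
meth_scale: logit          # or log2_fraction
ifn_rule: zscore_mean      # or mean_logexpr

# synthetic cohort overrides (any CohortSpec field); empty = study defaults
# (679/77/41/7 cohort, 5000 RNA / 5000+5000 methylation / 2434 protein
# features, pi_high 0.54, interaction LFC 4.7, ...)
cohort: {}
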