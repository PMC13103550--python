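# Methods

`dimorphix` implements a multi-omic analysis of sex-dimorphic disease
signatures, built around the case of systemic lupus erythematosus (SLE):
a disease nine times more common in women, yet often more severe in men.
The package's target phenomenon is aberrant X-chromosome inactivation
(XCI) biology in male patients — ectopic expression of the XIST long
non-coding RNA, hypermethylation of X-linked promoters and genes, and
modest transcriptional silencing of X-linked transcripts — detected
jointly across methylome, transcriptome and proteome layers of a
case/control cohort.

## The factorial model

Every modality is analysed with the same 2×2 factorial linear model per
feature *g*:

    y_g = β₀ + β₁·sex + β₂·disease + β₃·(sex × disease) + ε

with female = 0 / male = 1 and healthy control (HC) = 0 / SLE = 1. Under
this coding β₂ is the female SLE−HC effect, β₂+β₃ the male SLE−HC
effect, and β₃ the interaction, [Male SLE − Male HC] − [Female SLE −
Female HC]: the quantity that isolates disease responses that differ
between the sexes after accounting for baseline sex differences.

Per-feature residual variances s²_g (residual df d_g) are shrunk by
empirical Bayes toward a pooled prior (d₀, s₀²), estimated by moment
matching on log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the
model implies E[e] = log s₀² + ψ(d₀/2) − log(d₀/2) and Var[e] =
ψ′(d_g/2) + ψ′(d₀/2); ψ′(d₀/2) is solved by Newton inversion of the
trigamma function. The moderated statistic is

    t_g = c'β_g / (s̃_g · √(c'(X'WX)⁻¹c)),
    s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),  df = d₀ + d_g.

d₀ = 0 reproduces the ordinary t-test exactly (verified to machine
precision); d₀ = ∞ is complete shrinkage. When every s² is identical the
estimator returns (∞, the common value) — the degenerate limit rather
than the log-scale bias-corrected value, so that complete shrinkage in a
noiseless cohort uses the observed variance.

Significance: Benjamini–Hochberg FDR ≤ 0.1 **and** |fold change| > 1.5
(i.e. |LFC| > log₂1.5 ≈ 0.585). Sex-stratified calls are partitioned
into shared/sex-specific/discordant sets for the cohort summary.

### Scales per modality

* RNA-seq: counts are filtered by a CPM rule keyed to the smallest
  design cell (feature kept iff #samples with CPM ≥ min_count/median-lib-
  in-millions is at least the smallest group size — a deliberate
  simplification of edgeR's `filterByExpr`, which carries extra clauses
  such as `min.total.count` that this pipeline does not use), then
  log₂-CPM transformed with a 0.5 prior count, quantile normalized, and
  optionally precision-weighted by the inverse fourth power of a lowess
  trend of √(residual SD) on mean log-expression (the voom construction;
  one weight per feature). The transform order is fixed: count filter →
  quantile-normalized log-CPM → weights. Weights are on by default for
  RNA and never used for the other modalities.
* Methylation (promoter and gene level): region fractions in [0, 1] are
  modelled on the logit scale, log₂(m/(1−m)) with m clamped to
  [10⁻⁴, 1−10⁻⁴]. "Fold change" thresholds apply to this log₂-odds
  scale; a config switch (`meth_scale="log2_fraction"`) reverts to
  log₂ of the fraction. Promoter windows are 2000 bp upstream + 200 bp
  downstream of the TSS (strand-aware, clipped at the chromosome
  origin); region values are plain means of covered sites — no kernel
  smoothing.
* Protein (NPX, log₂ scale): vendor-flag failures are blanked, an assay
  is kept only when strictly more than 75% of samples exceed its limit
  of detection, and samples whose mean NPX falls more than 4 SD below
  the cohort mean (strict inequality, SD of per-sample means) are
  dropped. Sparse blanked values are median-imputed per assay before
  modelling.

## XIST bimodality and classification

The dip statistic of Hartigan & Hartigan measures the sup-norm distance
from the sample ECDF to the closest unimodal distribution function. It
is computed by the iterative greatest-convex-minorant / least-concave-
majorant algorithm on the sorted sample in count units (final value
halved and divided by n); D ∈ [1/(2n), 1/4]. The implementation is
cross-checked in the test suite against an independent linear-
programming oracle that solves the minimax fit over piecewise-linear
unimodal CDFs (mode at any data point, with or without a mode atom) —
agreement to 10⁻⁶ over a seeded battery including ties. p-values come
from Monte-Carlo draws of the uniform(0,1) null, p = (1 + #{D_null ≥
D_obs})/(n_mc + 1); the null depends only on n and may be precomputed
once for simulation studies (statistically identical, much cheaper).

Classification of male SLE samples into XIST-high/low uses the trough of
a Gaussian KDE with the Sheather–Jones solve-the-equation bandwidth
(pilot functionals at a = 1.24λn^(−1/7), b = 1.23λn^(−1/9), λ =
min(SD, IQR/1.349); the fixed-point equation solved by Brent root-
finding, falling back to Silverman's rule with a warning if no root is
bracketed in [10⁻³SD, 10SD]). The KDE is evaluated on a fixed 512-point
grid over the data range ± 4 bandwidths — wide enough that the trapezoid
integral stays within 10⁻³ of 1 even for one point. The threshold is the
density minimum strictly between the two **most prominent** local maxima
(ties leftmost). Using the two highest-density modes rather than the
outermost ones makes the rule robust to the tiny spurious bumps a stray
outlier raises far outside the mixture; with clean bimodal input the two
rules coincide. Unimodal input is an explicit error. Classification is
scale-covariant: any increasing affine transform of the data moves the
threshold with it.

qPCR Ct values are converted by the ΔΔCt convention — ΔCt = Ct_target −
Ct_reference, relative expression = 2^−(ΔCt − mean ΔCt of sex-matched
healthy controls) — and classified on the log₂ relative scale. Samples
missing qPCR are classified by an independently derived trough on the
RNA-seq values; each sample's source is recorded. Female-vs-male
variability comparisons use the Brown–Forsythe (median-centered) Levene
test.

## Chromosome-level enrichment

Chromosome gene sets place each annotated gene in exactly one set named
after its chromosome, except genes whose TSS lies inside a configured
pseudoautosomal interval (GRCh38 PAR1/PAR2 by default), which form a
separate "PAR" set. TSS membership (not span overlap) decides PAR
assignment.

Preranked GSEA walks the descending-LFC ranking with hit increments
|score|^w (w = 1, normalized over set members) and uniform miss
decrements; ES is the signed maximum deviation (positive wins exact
magnitude ties). The null is gene-label permutation (random same-size
sets, vectorized); NES divides ES by the mean |null ES| of the same
sign; the p-value is the one-sided add-one fraction of the same-sign
null portion — the convention under which null p-values are
approximately uniform — and FDR is Benjamini–Hochberg across the
reported set family (simpler than the original GSEA FDR). Sign
convention: rankings are by contrast LFC, so positive NES in a
methylation modality reads as enriched hypermethylation and negative NES
in transcripts/proteins as enriched downregulation.

Over-representation uses the exact hypergeometric tail P(overlap ≥ k).
X-linkage summaries report k/n fractions with their hypergeometric
enrichment p; the XCI-panel summary counts panel genes down-regulated at
FDR < 0.1 with and without the fold-change threshold.

## Deconvolution benchmark

Bulk expression is TPM-normalized (count/length rates scaled to 10⁶ per
sample) and modelled as y ≈ Rw over the genes shared with a reference
profile; built-in solvers are NNLS and OLS (negatives clipped, raw
weights kept), both renormalized to proportions summing to 1. Further
algorithms plug in through the same callable signature. Candidate
(reference, method) pairs are scored by the mean of the Pearson
correlations between estimated and flow-cytometry B-cell and NK-cell
proportions (ties broken by the B-cell correlation); pairs with constant
estimates are excluded with a warning. The mean-of-two-correlations
score operationalizes "high concordance with B and NK"; only those two
gates are scored because the mapping of finer deconvolution subsets onto
flow gates is not defined.

## Clinical screens

Numeric variables: two-sided Wilcoxon rank-sum per declared group pair
(exact enumeration when min(n) ≤ 10 and tie-free, otherwise the normal
approximation with tie and continuity corrections). Categorical
variables: Pearson chi-square without continuity correction, flagged
when any expected count is below 5. Feature–covariate screens use
Spearman correlation (average ranks, t-approximation p), pooled and
sex-stratified. Each declared family (numeric screen, categorical
screen, correlation screen — per group pair) is BH-corrected separately.
The interferon signature is the per-sample mean of per-gene z-scores
over MX1, OAS3, LY6E, USP18, IFI44 and DDX60 (constant genes dropped; a
mean-log-expression rule is available behind a config key).

## The synthetic cohort generator

The generator emits the four-cell cohort the analysis assumes — defaults
679 female SLE / 77 female HC / 41 male SLE / 7 male HC — with planted,
recoverable structure:

* RNA counts are negative binomial (dispersion 0.05) around log-normal
  baselines (log₂-CPM ~ N(5, 2) clipped to [0, 12]), with log-normal
  library sizes (CV 0.3). Baseline compositions are rescaled so planted
  CPMs sum to 10⁶ per column: planted log-CPM values then translate into
  counts at the intended depth even though only a few thousand genes are
  simulated.
* The XIST-like transcript: high in all females (log₂-CPM 9, +0.12 in
  SLE, plus SLE-only extra variability of SD 0.4 so the female variance
  comparison has signal); low in healthy males (log₂-CPM 3, chosen
  moderately expressed so the planted interaction is recoverable by a
  log-CPM estimator without the zero-count floor dominating); bimodal in
  male SLE — a two-component mixture with weight π_high = 0.54 on the
  elevated mode, mode separation 6 within-mode SDs, and the elevated
  shift derived from the target mixture-mean interaction effect of 4.7:
  shift = (4.7 + 0.12)/0.54. The within-mode SD is a free parameter, not
  a claim about real spread.
* Interferon module: the six signature genes plus 44 companions up 1.2
  log₂ units in SLE of both sexes. X-linked transcripts: half are down
  0.4 log₂ in male SLE only.
* Methylation: logit-normal fractions (baseline log₂-odds ~ N(−1, 1.5),
  within-feature SD 0.5); 80% of X-linked features gain +1.5 log₂-odds
  in male SLE only; two autosomal features lose 1.0 in SLE of both
  sexes (the shared interferon-locus hypomethylation analogue).
* Protein: Gaussian NPX (SD 0.6), 2434 assays of which 66 are X-linked
  (sparse X coverage, so protein-level X enrichment is expected to be
  underpowered — matching the modality contrast the analysis reports);
  33 shared up, 3 shared down, 223 female-only and 56 male-only effects
  of ±1 NPX; 8% of assays sit below their LOD by construction and are
  removed by the QC filter; 0.5% of measurements carry FAIL flags.
* A subset of genes (300 by default) is generated as an explicit mixture
  of an emitted 6-cell-type reference profile with per-sample Dirichlet
  proportions (whole-blood-like concentrations); the neutrophil fraction
  co-varies negatively with XIST in females only. Flow tables carry the
  true B/NK/T4/T8 proportions plus noise.
* qPCR: Ct = 30 − log₂(expression) + N(0, 0.15); three male SLE samples
  lack qPCR and exercise the RNA-seq fallback. Clinical variables are
  noisy monotone transforms of latent disease activity and XIST class
  (95 numeric, 31 categorical, mostly pure noise). Karyotypes are
  euploid except one planted XXY male and one XO female, which drive the
  X/autosome coverage ratios (0.5× for XY/XO, 1× for XX/XXY) used by
  sex QC.

Ground truth (true per-contrast effects, latent classes, proportions,
karyotypes, expected per-cell means) is emitted alongside and consumed
only by tests. Under `zero_noise=True` every group mean equals its
planted value exactly and the generator is bit-reproducible per seed.

What the generator does **not** emulate: read-level data, batch and
plate effects, genuine inter-feature correlation beyond the composition
genes, missingness mechanisms other than the planted qPCR gaps, and the
heavy-tailed outliers of real clinical chemistry. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to everything real cohorts contain.

## Simulation studies and their sizes

The validation studies are sized to run comfortably on one CPU:
dip-test calibration shares one precomputed 10,000-draw null per sample
size across its 1000 size replicates; classifier recovery uses 100
mixtures of n = 41; interaction recovery uses 20–50 full-scale cohorts
of 5000 transcripts; the silencing scan uses 10–20 cohorts of 500
methylation features with 500-permutation GSEA (the single-analysis
default remains 10,000 permutations); the deconvolution benchmark uses
20 replicates. The interaction-calibration cohorts exclude the
composition-driven genes: their shared latent proportions violate the
independent-feature assumption of the FDR calculation and are exercised
separately in the deconvolution study.

Two permutation variants of the silencing-scan negative control behave
differently and both are documented: permuting whole sample columns
preserves across-feature coherence, so random imbalance in where the 41
truly-affected samples land shifts every planted X feature together and
the X set can remain nominally enriched (the well-known
anticonservativeness of gene-permutation GSEA under inter-feature
correlation); permuting each feature's sample labels independently
destroys that coherence and yields the expected quiet null. The shipped
control uses the per-feature variant.

## Numerical choices and edge cases

* Residual variances are floored at 10⁻¹² before moderation; trigamma
  inversion uses asymptotic shortcuts outside [10⁻⁶, 10⁷].
* Quantile normalization assigns tied values the mean of their
  reference quantiles; a single-column matrix is returned unchanged.
* Voom weights are floored at 10⁻⁶ and fall back to unit weights (with
  a warning) below 50 features.
* GSEA falls back to unweighted scoring when all ranking scores are
  zero; sets outside [5, 5000] after universe intersection are skipped.
* The ES tie rule prefers the positive deviation, with a 10⁻¹² guard so
  floating-point noise cannot flip the sign of an exact tie.
* The dip test requires n ≥ 4 and a non-degenerate sample; the SJ
  bandwidth requires n ≥ 5 and positive variance.
* Sex-QC tolerance 0.25 splits the 0.5 vs 1.0 expected X/autosome
  ratios symmetrically.

## Known limitations

* The moderated-t far tail is anticonservative for count data when one
  design cell is very small (here 7 male controls): negative-binomial
  skewness propagates into occasional outlying interaction estimates at
  realistically dispersed counts. The calibration study quantifies this
  (pooled null-feature FDR at nominal 0.1 stays near but not at the
  nominal level); analyses of such cohorts should read borderline
  interaction hits accordingly.
* Gene-label permutation GSEA ignores inter-feature correlation (see
  the negative-control discussion above).
* The dip-test null is the uniform distribution, as in the original
  formulation; it is conservative against unimodal but non-uniform
  nulls.
* Only B and NK gates anchor the deconvolution benchmark; rare-subset
  estimates (dendritic cells, plasmablasts) are reported but should not
  be over-interpreted.

## A note on quantile normalization and extreme transcripts

Quantile normalization assumes every sample shares one expression
distribution. When a single transcript is enormously differential in a
small subgroup — as XIST is in XIST-high male SLE — that assumption is
wrong in the top tail, and QN partially flattens the very signal of
interest. The effect scales with the rank-space sparsity of the tail: at
this package's default 5000 simulated transcripts it compresses the
planted interaction by roughly 0.26 log2 units, while at genome-scale
feature counts it is much smaller. For this reason the interaction
recovery study fits unnormalized log-CPM (isolating the estimator),
while the pipeline keeps quantile normalization in its default chain;
analysts chasing a single extreme transcript should compare both.
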