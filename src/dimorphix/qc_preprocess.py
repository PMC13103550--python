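"""Modality-specific QC filters, normalization, region summarization, sex QC.

The proteomic filters mirror a standard Olink NPX workflow: measurements
failing vendor QC are blanked, assays are kept only when strictly more than
``min_frac`` of samples lie strictly above the assay's limit of detection
(LOD), and whole samples are excluded when their mean NPX falls more than
``k_sd`` standard deviations below the cohort mean.

RNA-seq count preprocessing re-specifies the usual filterByExpr /
quantile-normalized voom chain as three explicit operations: a CPM-cutoff
low-count filter keyed to the smallest group size, quantile normalization
of log-CPM, and mean-variance precision weights from a lowess trend of
residual spread. filterByExpr's extra clauses (min.total.count etc.) are a
deliberate simplification here; the fixed transform order is
count filter -> quantile-normalized log-CPM -> voom weights.

Sex QC compares each sample's X/autosome mean-coverage ratio with the value
expected from its reported sex (0.5 for XY males, 1.0 for XX females);
samples off by more than ``tol`` are flagged anomalous (XXY- or XO-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .annotation_io import FeatureMatrix

__all__ = [
    "LodTable",
    "SexQcReport",
    "filter_npx_by_lod",
    "exclude_low_expression_samples",
    "filter_low_counts",
    "quantile_normalize",
    "log_cpm",
    "voom_weights",
    "summarize_methylation_regions",
    "sex_qc_read_depth",
    "logit_transform",
]

MIN_FEATURES_FOR_TREND = 50
WEIGHT_FLOOR = 1e-6


@dataclass
class LodTable:
    """assay_id -> limit of detection (NPX units)."""

    lod: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.lod.to_numpy(dtype=float)).all():
            raise ValueError("LOD values must be finite")


@dataclass
class SexQcReport:
    sample_id: str
    ratio: float
    expected: float
    anomalous: bool

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("X/autosome coverage ratio must be positive")


def filter_npx_by_lod(
    matrix: FeatureMatrix,
    lod: LodTable,
    flags: pd.DataFrame | None = None,
    min_frac: float = 0.75,
) -> FeatureMatrix:
    """Keep assays whose NPX exceeds the LOD in strictly more than
    ``min_frac`` of samples; FAIL-flagged measurements are blanked first.

    ``flags``, when given, is a features-x-samples frame of {"PASS","FAIL"}.
    Blanked (missing) measurements count as not-above-LOD.
    """
    if matrix.modality != "protein_npx":
        raise ValueError("LOD filtering applies to protein_npx matrices")
    values = matrix.values.copy()
    missing_lod = values.index.difference(lod.lod.index)
    if len(missing_lod):
        raise ValueError(f"assays without LOD: {list(missing_lod)[:5]}")
    if flags is not None:
        fail = flags.reindex(index=values.index, columns=values.columns) == "FAIL"
        values = values.mask(fail)
    lods = lod.lod.reindex(values.index)
    above = values.gt(lods, axis=0)  # NaN compares False
    frac_above = above.sum(axis=1) / values.shape[1]
    kept = frac_above > min_frac
    return FeatureMatrix(values=values.loc[kept], modality="protein_npx")


def exclude_low_expression_samples(
    matrix: FeatureMatrix, k_sd: float = 4.0
) -> list[str]:
    """Samples whose mean NPX lies strictly below cohort mean − k_sd·SD.

    The SD is that of the per-sample means. Samples at exactly −k_sd·SD are
    retained (strict inequality). A zero-SD cohort excludes nobody.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sample_means = matrix.values.mean(axis=0, skipna=True)
    mu, sd = sample_means.mean(), sample_means.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return []
    cutoff = mu - k_sd * sd
    return list(sample_means.index[sample_means < cutoff])


def filter_low_counts(
    counts: FeatureMatrix, group_labels: pd.Series, min_count: float = 10.0
) -> list[str]:
    """Low-count filter: keep a feature iff the number of samples with
    CPM >= min_count / (median library size in millions) is at least the
    smallest group size."""
    if counts.modality != "rna_counts":
        raise ValueError("count filtering applies to rna_counts matrices")
    labels = group_labels.reindex(counts.values.columns)
    group_sizes = labels.value_counts()
    if len(group_sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (group_sizes == 0).any():
        raise ValueError("empty group")
    lib_sizes = counts.values.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    cutoff = min_count / (lib_sizes.median() / 1e6)
    cpm = counts.values.div(lib_sizes, axis=1) * 1e6
    n_ok = (cpm >= cutoff).sum(axis=1)
    kept = n_ok >= group_sizes.min()
    return list(counts.values.index[kept])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean of order statistics.

    Ties within a column receive the mean of their reference quantiles.
    A single-column input is returned unchanged.
    """
    if values.isna().any().any():
        raise ValueError("quantile normalization requires complete data")
    if values.shape[1] < 2:
        return values.copy()
    arr = values.to_numpy(dtype=float)
    order = np.sort(arr, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = reference[lo] * (1 - frac) + reference[np.minimum(hi, n - 1)] * frac
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_cpm(counts: FeatureMatrix, prior: float = 0.5) -> FeatureMatrix:
    """log2 counts-per-million with a prior count:
    log2((count + prior) / (libsize + 2*prior) * 1e6)."""
    vals = counts.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative counts")
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    out = np.log2((vals + prior) / (lib + 2 * prior) * 1e6)
    return FeatureMatrix(
        values=pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        modality="rna_logexpr",
    )


def voom_weights(
    logexpr: FeatureMatrix, design: np.ndarray, span: float = 0.5
) -> pd.DataFrame:
    """Precision weights from the fitted mean-variance trend.

    Per feature, the residual standard deviation of the design fit is
    square-rooted and lowess-smoothed against mean log-expression; the
    inverse fourth power of the interpolated trend (i.e. inverse predicted
    variance) is the weight, floored at a small positive constant. All
    observations of one feature share its weight; with fewer than 50
    features the trend is not estimable and unit weights are returned.
    """
    y = logexpr.values.to_numpy(dtype=float)
    n_features, n_samples = y.shape
    X = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if n_samples - rank <= 0:
        raise ValueError("no residual degrees of freedom")
    if n_features < MIN_FEATURES_FOR_TREND:
        import warnings

        warnings.warn("too few features to fit a mean-variance trend; unit weights")
        return pd.DataFrame(
            np.ones_like(y), index=logexpr.values.index, columns=logexpr.values.columns
        )
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    resid = y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / (n_samples - rank)
    mean_log = y.mean(axis=1)
    sqrt_sd = np.sqrt(np.sqrt(s2))
    trend = lowess(sqrt_sd, mean_log, frac=span, return_sorted=True)
    fitted_quarter_sd = np.interp(mean_log, trend[:, 0], trend[:, 1])
    fitted_quarter_sd = np.clip(fitted_quarter_sd, WEIGHT_FLOOR**0.25, None)
    w = 1.0 / fitted_quarter_sd**4
    w = np.clip(w, WEIGHT_FLOOR, None)
    weights = np.repeat(w[:, None], n_samples, axis=1)
    return pd.DataFrame(weights, index=logexpr.values.index, columns=logexpr.values.columns)


def summarize_methylation_regions(
    site_meth: pd.DataFrame,
    site_positions: pd.DataFrame,
    regions: pd.DataFrame,
    modality: str = "promoter_meth",
) -> FeatureMatrix:
    """Mean site methylation within each region's half-open span.

    ``site_meth``: sites x samples fractions; ``site_positions``: per site
    (chromosome, position), sorted by position within each chromosome;
    ``regions``: (gene_id, chromosome, start, end). Regions covering no
    site get missing values.
    """
    for chrom, sub in site_positions.groupby("chromosome", sort=False):
        if not sub["position"].is_monotonic_increasing:
            raise ValueError(f"sites not sorted by position on chromosome {chrom}")
    out = {}
    for row in regions.itertuples(index=False):
        on_chrom = site_positions["chromosome"] == row.chromosome
        pos = site_positions.loc[on_chrom, "position"]
        in_region = pos[(pos >= row.start) & (pos < row.end)].index
        if len(in_region) == 0:
            out[row.gene_id] = pd.Series(np.nan, index=site_meth.columns)
        else:
            out[row.gene_id] = site_meth.loc[in_region].mean(axis=0)
    values = pd.DataFrame(out).T
    values.index.name = "feature_id"
    return FeatureMatrix(values=values, modality=modality)


def sex_qc_read_depth(
    depths: pd.DataFrame, reported_sex: pd.Series, tol: float = 0.25
) -> list[SexQcReport]:
    """Flag samples whose X/autosome coverage ratio is inconsistent with
    their reported sex.

    ``depths``: samples x chromosomes mean coverage (must contain "X" and
    at least one autosome). Expected ratio: 0.5 for males, 1.0 for females;
    anomalous iff |ratio − expected| > tol.
    """
    if "X" not in depths.columns:
        raise ValueError("depth table lacks X-chromosome coverage")
    autosomes = [c for c in depths.columns if c not in ("X", "Y", "MT")]
    if not autosomes:
        raise ValueError("depth table lacks autosomal coverage")
    auto_mean = depths[autosomes].mean(axis=1)
    if (auto_mean <= 0).any():
        raise ValueError("autosomal coverage must be positive")
    reports = []
    for sample in depths.index:
        sex = reported_sex.loc[sample]
        expected = 0.5 if sex == "M" else 1.0
        ratio = float(depths.loc[sample, "X"] / auto_mean.loc[sample])
        reports.append(
            SexQcReport(
                sample_id=str(sample),
                ratio=ratio,
                expected=expected,
                anomalous=abs(ratio - expected) > tol,
            )
        )
    return reports


def logit_transform(meth: FeatureMatrix, eps: float = 1e-4) -> pd.DataFrame:
    """Logit of methylation fractions, clamped to [eps, 1-eps].

    Differential analysis of region methylation runs on this scale; the
    clamp keeps boundary fractions finite.
    """
    vals = meth.values.to_numpy(dtype=float)
    clamped = np.clip(vals, eps, 1 - eps)
    return pd.DataFrame(
        np.log2(clamped / (1 - clamped)),
        index=meth.values.index,
        columns=meth.values.columns,
    )
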