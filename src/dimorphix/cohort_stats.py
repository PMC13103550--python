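"""Interferon signature scoring and clinical screening statistics.

The type-I interferon signature aggregates six interferon-stimulated
genes (MX1, OAS3, LY6E, USP18, IFI44, DDX60): each gene is z-scored
across samples and a sample's score is the mean of its available gene
z-scores (an alternative mean-log-expression rule is available).

Clinical screens run Wilcoxon rank-sum tests over numeric variables and
Pearson chi-square tests over categorical variables for declared group
pairs, and Spearman correlations between a feature (XIST expression, say)
and covariates, each family Benjamini-Hochberg-corrected separately.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .factorial_de import bh_adjust

__all__ = [
    "IFN_GENES",
    "ifn_signature",
    "spearman_corr",
    "wilcoxon_rank_sum",
    "chisq_test",
    "clinical_screen",
    "correlate_features_with_covariates",
]

logger = logging.getLogger(__name__)

IFN_GENES = ("MX1", "OAS3", "LY6E", "USP18", "IFI44", "DDX60")


def ifn_signature(
    logexpr: pd.DataFrame,
    genes: tuple = IFN_GENES,
    rule: str = "zscore_mean",
) -> pd.Series:
    """Per-sample interferon signature score.

    ``rule="zscore_mean"`` (default): mean across genes of per-gene
    z-scores; genes constant across samples are dropped (z undefined).
    ``rule="mean_logexpr"``: plain mean of the genes' log expression.
    Missing genes are reported via logging; if none are present, error.
    """
    present = [g for g in genes if g in logexpr.index]
    missing = [g for g in genes if g not in logexpr.index]
    if missing:
        logger.info("IFN signature genes absent from matrix: %s", missing)
    if not present:
        raise ValueError("none of the signature genes are present")
    sub = logexpr.loc[present]
    if rule == "mean_logexpr":
        return sub.mean(axis=0)
    if rule != "zscore_mean":
        raise ValueError(f"unknown aggregation rule {rule!r}")
    sds = sub.std(axis=1, ddof=1)
    usable = sds > 0
    if not usable.any():
        raise ValueError("all signature genes constant across samples")
    sub = sub.loc[usable]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    return z.mean(axis=0)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with the
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError("need at least 4 paired finite values")
    rx, ry = stats.rankdata(x[ok]), stats.rankdata(y[ok])
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null enumeration when min(n_a, n_b) <= 10 and the pooled data
    are tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chisq_test(table) -> tuple[float, int, float, bool]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns (chi2, df, p, low_expected_warning); the flag is set when any
    expected count falls below 5. Zero margins are an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p), bool((expected < 5).any())


def clinical_screen(
    samples: pd.DataFrame,
    groupings: dict[str, tuple[pd.Series, pd.Series]],
    numeric_vars: list[str],
    categorical_vars: list[str],
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Wilcoxon/chi-square screens over clinical variables for each group
    pair, BH-corrected within each (test family x group pair).

    ``groupings`` maps a pair name to two boolean sample masks. Variables
    with too few non-missing values in either group are skipped and
    logged.
    """
    rows = []
    for pair_name, (mask_a, mask_b) in groupings.items():
        fam_numeric = []
        for var in numeric_vars:
            a = samples.loc[mask_a, var].dropna()
            b = samples.loc[mask_b, var].dropna()
            if len(a) < min_per_group or len(b) < min_per_group:
                logger.info("skipping %s in %s: too few values", var, pair_name)
                continue
            stat, p = wilcoxon_rank_sum(a, b)
            fam_numeric.append((var, "wilcoxon", stat, p))
        fam_cat = []
        for var in categorical_vars:
            sub_a = samples.loc[mask_a, var].dropna()
            sub_b = samples.loc[mask_b, var].dropna()
            if len(sub_a) < min_per_group or len(sub_b) < min_per_group:
                logger.info("skipping %s in %s: too few values", var, pair_name)
                continue
            levels = sorted(set(sub_a) | set(sub_b))
            if len(levels) < 2:
                logger.info("skipping %s in %s: single level", var, pair_name)
                continue
            table = np.array(
                [
                    [(sub_a == lv).sum() for lv in levels],
                    [(sub_b == lv).sum() for lv in levels],
                ]
            )
            try:
                chi2, _, p, _ = chisq_test(table)
            except ValueError:
                logger.info("skipping %s in %s: degenerate table", var, pair_name)
                continue
            fam_cat.append((var, "chisq", chi2, p))
        for family in (fam_numeric, fam_cat):
            if not family:
                continue
            fdrs = bh_adjust(np.array([f[3] for f in family]))
            for (var, test, stat, p), q in zip(family, fdrs):
                rows.append(
                    {
                        "variable": var,
                        "test": test,
                        "group_pair": pair_name,
                        "statistic": stat,
                        "p": p,
                        "fdr": float(q),
                    }
                )
    return pd.DataFrame(rows)


def correlate_features_with_covariates(
    feature: pd.Series,
    covariates: pd.DataFrame,
    stratify_by: pd.Series | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman screen of one feature against covariates, BH within each
    declared family (pooled, or one family per stratum).

    Returns rows (stratum, covariate, rho, p, fdr, n); stratum is
    "pooled" when unstratified.
    """
    strata: dict[str, pd.Index]
    if stratify_by is None:
        strata = {"pooled": feature.index}
    else:
        strata = {
            str(level): feature.index[stratify_by.reindex(feature.index) == level]
            for level in pd.unique(stratify_by.dropna())
        }
    rows = []
    for stratum, idx in strata.items():
        fam = []
        for var in covariates.columns:
            x = feature.reindex(idx)
            y = covariates.loc[idx, var] if len(idx) else pd.Series(dtype=float)
            ok = x.notna() & y.notna()
            if ok.sum() < min_n:
                logger.info("skipping %s in stratum %s: n=%d", var, stratum, ok.sum())
                continue
            try:
                rho, p = spearman_corr(x[ok], y[ok])
            except ValueError:
                continue
            fam.append((var, rho, p, int(ok.sum())))
        if not fam:
            continue
        fdrs = bh_adjust(np.array([f[2] for f in fam]))
        for (var, rho, p, n), q in zip(fam, fdrs):
            rows.append(
                {
                    "stratum": stratum,
                    "covariate": var,
                    "rho": rho,
                    "p": p,
                    "fdr": float(q),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
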