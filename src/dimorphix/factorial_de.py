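"""Feature-wise factorial linear models with empirical-Bayes moderation.

The design is the 2x2 factorial  intercept + sex + disease + sex:disease
with female=0/male=1 and HC=0/SLE=1, so the coefficients are directly
interpretable: the disease coefficient is the female SLE-vs-HC effect, and
the interaction coefficient is [Male SLE - Male HC] - [Female SLE - Female HC].

Per feature an ordinary (optionally precision-weighted) least-squares fit
yields coefficients, residual variance s^2 and residual df d_g. Variances
are then shrunk toward a pooled prior (d0, s0^2) estimated by moment
matching on log s^2 (the scaled-chi-square hierarchical model: solve the
digamma/trigamma moment equations), and contrasts are tested with the
moderated t-statistic

    t = c'beta / (s_post * sqrt(c' (X'WX)^{-1} c)),
    s_post^2 = (d0 s0^2 + d_g s^2) / (d0 + d_g),   df = d0 + d_g.

Benjamini-Hochberg adjustment and the FDR <= 0.1, |FC| > 1.5 significance
rule follow, plus the Venn partition of per-sex significant calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "VariancePrior",
    "FeatureFits",
    "make_design",
    "make_group_design",
    "fit_feature_models",
    "estimate_variance_prior",
    "moderated_t",
    "bh_adjust",
    "contrast_table",
    "call_significant",
    "venn_partition",
    "CONTRASTS",
]

S2_FLOOR = 1e-12

#: Contrast vectors on the (intercept, sex, disease, sex:disease) coding.
CONTRASTS = {
    "female_SLE_vs_HC": np.array([0.0, 0.0, 1.0, 0.0]),
    "male_SLE_vs_HC": np.array([0.0, 0.0, 1.0, 1.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
}


@dataclass
class VariancePrior:
    d0: float  # prior degrees of freedom, may be inf
    s02: float  # prior variance

    def __post_init__(self) -> None:
        # d0 = 0 is the no-moderation limit (ordinary t); estimation always
        # returns d0 > 0 but the limit is accepted here.
        if not self.d0 >= 0:
            raise ValueError("prior df must be non-negative")
        if not self.s02 > 0:
            raise ValueError("prior variance must be positive")


@dataclass
class FeatureFits:
    """Least-squares results for all features of one modality."""

    feature_ids: list
    beta: np.ndarray  # features x coefficients
    s2: np.ndarray  # residual variances
    df_residual: float
    unscaled_cov: np.ndarray | None  # (X'X)^{-1}, shared (unweighted fit)
    unscaled_var: np.ndarray | None = None  # per-feature c-variance cache (weighted)
    design_columns: tuple = ("intercept", "sex", "disease", "sex:disease")

    def contrast_variance_factor(self, contrast: np.ndarray) -> np.ndarray:
        """c'(X'WX)^{-1}c per feature (constant across features when
        the fit was unweighted)."""
        c = np.asarray(contrast, dtype=float)
        if self.unscaled_var is not None:
            # per-feature (X'WX)^{-1} stored as stacked matrices
            return np.einsum("i,fij,j->f", c, self.unscaled_var, c)
        factor = float(c @ self.unscaled_cov @ c)
        return np.full(len(self.feature_ids), factor)


def make_design(sex: pd.Series, disease: pd.Series) -> np.ndarray:
    """2x2 factorial design matrix; sex in {F, M}, disease in {HC, SLE}."""
    male = (sex == "M").to_numpy(dtype=float)
    sle = (disease == "SLE").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(male), male, sle, male * sle])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: a factorial cell is empty")
    return X


def make_group_design(groups: pd.Series, levels: list[str]) -> np.ndarray:
    """One-hot group-means design (no intercept) for subgroup contrasts,
    e.g. the 3-level male factor (HC, XIST-low, XIST-high)."""
    mats = [(groups == lv).to_numpy(dtype=float) for lv in levels]
    X = np.column_stack(mats)
    if (X.sum(axis=0) == 0).any():
        raise ValueError("empty group level in design")
    return X


def fit_feature_models(
    values: pd.DataFrame, design: np.ndarray, weights: pd.DataFrame | None = None
) -> FeatureFits:
    """Per-feature (weighted) least squares.

    ``values``: features x samples on the analysis scale (log-CPM, logit
    methylation, NPX). ``weights``: optional positive per-observation
    weights aligned with ``values``.
    """
    y = values.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design")
    df_resid = n - rank
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if weights is None:
        pinv = np.linalg.pinv(X)
        beta = y @ pinv.T
        resid = y - beta @ X.T
        s2 = (resid**2).sum(axis=1) / df_resid
        cov = np.linalg.inv(X.T @ X)
        return FeatureFits(
            feature_ids=list(values.index),
            beta=beta,
            s2=np.maximum(s2, 0.0),
            df_residual=float(df_resid),
            unscaled_cov=cov,
        )
    w = weights.to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    n_feat = y.shape[0]
    beta = np.empty((n_feat, X.shape[1]))
    s2 = np.empty(n_feat)
    covs = np.empty((n_feat, X.shape[1], X.shape[1]))
    # X'WX = X' diag(w_f) X, vectorized over features via einsum
    xtwx = np.einsum("ni,fn,nj->fij", X, w, X)
    xtwy = np.einsum("ni,fn,fn->fi", X, w, y)
    for f in range(n_feat):
        covs[f] = np.linalg.inv(xtwx[f])
        beta[f] = covs[f] @ xtwy[f]
        resid = y[f] - X @ beta[f]
        s2[f] = float((w[f] * resid**2).sum() / df_resid)
    return FeatureFits(
        feature_ids=list(values.index),
        beta=beta,
        s2=np.maximum(s2, 0.0),
        df_residual=float(df_resid),
        unscaled_cov=None,
        unscaled_var=covs,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing),
    with asymptotic shortcuts at the extremes where trigamma(x) ~ 1/x
    (small y) or ~ 1/x^2 (large y)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return float(1.0 / np.sqrt(y))
    if y < 1e-6:
        return float(1.0 / y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df_residual: float) -> VariancePrior:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Under the hierarchical model s^2 | sigma^2 ~ sigma^2 chi^2_d/d with
    1/sigma^2 ~ chi^2_{d0}/(d0 s0^2), e = log s^2 - digamma(d/2) + log(d/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2); the sample moments of e give (d0, s0^2).
    d0 = inf (complete shrinkage) when the spread of log s^2 does not exceed
    its sampling floor.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 30:
        raise ValueError("need at least 30 features to estimate the prior")
    if (s2 <= 0).all():
        raise ValueError("all residual variances are zero")
    s2 = np.maximum(s2, S2_FLOOR)
    if np.ptp(s2) == 0:
        # zero-spread limit: complete shrinkage onto the common variance
        return VariancePrior(d0=np.inf, s02=float(s2[0]))
    d = df_residual
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_bar = float(e.mean())
    n = len(e)
    e_var = float(((e - e_bar) ** 2).sum() / (n - 1)) - float(special.polygamma(1, d / 2))
    if e_var <= 0:
        return VariancePrior(d0=np.inf, s02=float(np.exp(e_bar)))
    half_d0 = _trigamma_inverse(e_var)
    if not np.isfinite(half_d0):
        return VariancePrior(d0=np.inf, s02=float(np.exp(e_bar)))
    d0 = 2 * half_d0
    s02 = float(np.exp(e_bar + special.digamma(half_d0) - np.log(half_d0)))
    return VariancePrior(d0=d0, s02=s02)


def moderated_t(
    fits: FeatureFits, prior: VariancePrior, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p for one contrast.

    d0 = 0 degenerates to the ordinary t-test; d0 = inf uses s0^2 for every
    feature. (d0 = 0 is accepted here for that limiting-case use even
    though estimate_variance_prior never returns it.)
    """
    c = np.asarray(contrast, dtype=float)
    effect = fits.beta @ c
    var_factor = fits.contrast_variance_factor(c)
    d_g = fits.df_residual
    d0 = prior.d0
    s2 = np.maximum(fits.s2, S2_FLOOR)
    if np.isinf(d0):
        s2_post = np.full_like(s2, prior.s02)
        df_total = np.inf
    else:
        s2_post = (d0 * prior.s02 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s2_post * var_factor)
    t = effect / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def contrast_table(
    fits: FeatureFits,
    prior: VariancePrior,
    contrast: np.ndarray,
    contrast_name: str,
    fdr_max: float = 0.1,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Per-feature LFC / moderated t / p / FDR / significance for one contrast."""
    c = np.asarray(contrast, dtype=float)
    lfc = fits.beta @ c
    t, p = moderated_t(fits, prior, c)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "feature_id": fits.feature_ids,
            "contrast": contrast_name,
            "lfc": lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
        }
    ).set_index("feature_id")
    table["significant"] = call_significant(table, fdr_max=fdr_max, fc_min=fc_min)
    return table


def call_significant(
    table: pd.DataFrame, fdr_max: float = 0.1, fc_min: float = 1.5
) -> pd.Series:
    """FDR <= fdr_max AND |LFC| > log2(fc_min)."""
    return (table["fdr"] <= fdr_max) & (table["lfc"].abs() > np.log2(fc_min))


def venn_partition(female: pd.DataFrame, male: pd.DataFrame) -> dict[str, int]:
    """Partition significant calls of the two sex-stratified contrasts.

    Returns counts for female_only_up/down, male_only_up/down,
    shared_up/down (significant in both, concordant sign) and discordant
    (significant in both, opposite signs). Exhaustive and mutually
    exclusive over significant features.
    """
    if not female.index.equals(male.index):
        raise ValueError("mismatched feature universes")
    f_sig = female["significant"].to_numpy(dtype=bool)
    m_sig = male["significant"].to_numpy(dtype=bool)
    f_up = female["lfc"].to_numpy() > 0
    m_up = male["lfc"].to_numpy() > 0
    both = f_sig & m_sig
    return {
        "female_only_up": int((f_sig & ~m_sig & f_up).sum()),
        "female_only_down": int((f_sig & ~m_sig & ~f_up).sum()),
        "male_only_up": int((m_sig & ~f_sig & m_up).sum()),
        "male_only_down": int((m_sig & ~f_sig & ~m_up).sum()),
        "shared_up": int((both & f_up & m_up).sum()),
        "shared_down": int((both & ~f_up & ~m_up).sum()),
        "discordant": int((both & (f_up != m_up)).sum()),
    }
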