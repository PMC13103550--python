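"""Reference-based immune-cell deconvolution of bulk expression and the
flow-cytometry benchmark that selects a reference/method pair.

Bulk expression is modelled as a non-negative mixture of cell-type mean
profiles on the TPM scale: y ~ R w with w >= 0. Two solvers are built in
(non-negative least squares and ordinary least squares with negative
weights clipped); further algorithms can be registered through the same
callable interface. Candidate (reference, method) pairs are benchmarked by
Pearson correlation of their estimated proportions against flow-cytometry
gates; the selection score is the mean of the B-cell and NK-cell
correlations, the two gates the benchmark trusts most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ReferenceProfile",
    "ProportionEstimate",
    "BenchmarkResult",
    "tpm_normalize",
    "deconvolve_nnls",
    "deconvolve_ols",
    "benchmark_deconvolution",
    "METHODS",
]


@dataclass
class ReferenceProfile:
    """Genes x cell-type mean expression (TPM scale)."""

    values: pd.DataFrame
    name: str

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("reference profiles must be non-negative")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 cell types")


@dataclass
class ProportionEstimate:
    """Samples x cell-type proportions (rows sum to 1)."""

    proportions: pd.DataFrame
    method: str
    reference: str
    raw: pd.DataFrame | None = None  # pre-clipping weights (OLS)

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy()
        if (vals < -1e-12).any():
            raise ValueError("negative proportions")


@dataclass
class BenchmarkResult:
    correlations: pd.DataFrame  # (reference, method, cell_type) -> r
    selected: tuple[str, str]
    score: float


def tpm_normalize(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-rate normalization to 1e6 per sample."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero sample")
    return rate.div(totals, axis=1) * 1e6


def _shared_genes(expr: pd.DataFrame, ref: ReferenceProfile) -> pd.Index:
    shared = expr.index.intersection(ref.values.index)
    if len(shared) < ref.values.shape[1]:
        raise ValueError("fewer shared genes than cell types")
    return shared


def _renormalize(w: np.ndarray) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        return np.full_like(w, 1.0 / len(w))
    return w / total


def deconvolve_nnls(expr: pd.DataFrame, ref: ReferenceProfile) -> ProportionEstimate:
    """Per-sample non-negative least squares on the shared-gene intersection."""
    shared = _shared_genes(expr, ref)
    R = ref.values.loc[shared].to_numpy(dtype=float)
    out = {}
    for sample in expr.columns:
        y = expr.loc[shared, sample].to_numpy(dtype=float)
        w, _ = optimize.nnls(R, y)
        out[sample] = _renormalize(w)
    props = pd.DataFrame(out, index=ref.values.columns).T
    return ProportionEstimate(proportions=props, method="nnls", reference=ref.name)


def deconvolve_ols(expr: pd.DataFrame, ref: ReferenceProfile) -> ProportionEstimate:
    """Unconstrained least squares; negatives clipped to 0, renormalized.

    The raw (unclipped) weights are kept alongside. A collinear reference
    is an error.
    """
    shared = _shared_genes(expr, ref)
    R = ref.values.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("collinear reference columns")
    Y = expr.loc[shared].to_numpy(dtype=float)
    W, *_ = np.linalg.lstsq(R, Y, rcond=None)
    raw = pd.DataFrame(W.T, index=expr.columns, columns=ref.values.columns)
    clipped = np.clip(W, 0.0, None)
    props = np.apply_along_axis(_renormalize, 0, clipped).T
    return ProportionEstimate(
        proportions=pd.DataFrame(props, index=expr.columns, columns=ref.values.columns),
        method="ols",
        reference=ref.name,
        raw=raw,
    )


METHODS: dict[str, Callable[[pd.DataFrame, ReferenceProfile], ProportionEstimate]] = {
    "nnls": deconvolve_nnls,
    "ols": deconvolve_ols,
}


def benchmark_deconvolution(
    estimates: list[ProportionEstimate],
    flow: pd.DataFrame,
    gate_map: dict[str, str] | None = None,
    min_overlap: int = 10,
) -> BenchmarkResult:
    """Score candidate (reference, method) estimates against flow cytometry.

    ``flow``: samples x gates proportions; ``gate_map`` maps estimate
    cell-type columns to flow gate columns (default: identically named
    "B" and "NK" columns). Selection score = mean of r(B) and r(NK); ties
    break by r(B). Pairs with undefined correlations (constant estimates)
    are excluded with a warning.
    """
    gate_map = gate_map or {"B": "B", "NK": "NK"}
    rows = []
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for est in estimates:
        overlap = est.proportions.index.intersection(flow.index)
        if len(overlap) < min_overlap:
            raise ValueError(
                f"only {len(overlap)} samples shared with flow for "
                f"({est.reference}, {est.method})"
            )
        rs = {}
        ok = True
        for cell, gate in gate_map.items():
            x = est.proportions.loc[overlap, cell].to_numpy(dtype=float)
            y = flow.loc[overlap, gate].to_numpy(dtype=float)
            if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                import warnings

                warnings.warn(
                    f"constant estimates for {cell} in ({est.reference}, "
                    f"{est.method}); pair excluded"
                )
                ok = False
                break
            rs[cell] = float(stats.pearsonr(x, y)[0])
        if not ok:
            continue
        for cell, r in rs.items():
            rows.append(
                {
                    "reference": est.reference,
                    "method": est.method,
                    "cell_type": cell,
                    "r": r,
                }
            )
        b_cell = next(iter(gate_map))
        score = float(np.mean(list(rs.values())))
        scores[(est.reference, est.method)] = (score, rs[b_cell])
    if not scores:
        raise ValueError("no scorable (reference, method) pairs")
    selected = max(scores, key=lambda k: scores[k])
    return BenchmarkResult(
        correlations=pd.DataFrame(rows),
        selected=selected,
        score=scores[selected][0],
    )
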