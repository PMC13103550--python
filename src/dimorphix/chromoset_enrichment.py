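"""Preranked GSEA and hypergeometric over-representation against
chromosome/PAR gene sets; X-inactivation summary statistics.

Chromosome-level enrichment asks whether the genes of one chromosome
concentrate at an extreme of a contrast's log-fold-change ranking. The
running-sum enrichment score (ES) walks the descending-LFC list,
incrementing by |score|^w (normalized over set members) at hits and
decrementing uniformly at misses; ES is the signed maximum deviation. The
null comes from gene-label permutations (random same-size sets); NES
normalizes ES by the mean |null ES| of the same sign, p is the one-sided
add-one permutation fraction and FDR is Benjamini-Hochberg across the
reported set family.

Sign convention for the silencing scan: rankings are by the contrast LFC,
so a positive NES for a methylation modality means enriched
hypermethylation of that chromosome, while a negative NES for transcripts
or proteins means enriched downregulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .factorial_de import bh_adjust

__all__ = [
    "GseaResult",
    "OraResult",
    "rank_by_lfc",
    "gsea_preranked",
    "hypergeometric_ora",
    "chromosome_silencing_scan",
    "xlinked_fraction_summary",
    "xci_panel_summary",
]


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: list
    set_size: int


@dataclass
class OraResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K in universe
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    fdr: float = np.nan


def rank_by_lfc(table: pd.DataFrame) -> pd.DataFrame:
    """Order a contrast table by descending LFC.

    Ties break by ascending p, then lexicographic feature id, giving a
    strict total order. Returns a two-column frame (feature_id index,
    score) ready for :func:`gsea_preranked`.
    """
    if table.index.has_duplicates:
        raise ValueError("duplicate gene ids in contrast table")
    tmp = table.copy()
    tmp["_id"] = tmp.index
    tmp = tmp.sort_values(["lfc", "p", "_id"], ascending=[False, True, True])
    return pd.DataFrame({"score": tmp["lfc"]}, index=tmp.index)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized running-sum extrema for many same-size hit sets.

    ``positions``: (reps, K) sorted 0-based hit positions in the ranked
    list; ``weights``: per-position |score|^w over the whole list. Returns
    (es, extremum_position) per rep, where es is the signed maximum
    deviation of the running sum (candidate extrema occur at hit steps).
    """
    reps, k = positions.shape
    miss = 1.0 / (n - k)
    w_hits = weights[positions]
    totals = w_hits.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("zero total hit weight")
    cum = np.cumsum(w_hits, axis=1) / totals
    j = np.arange(k)
    after = cum - (positions - j) * miss  # value just after each hit
    before = after - w_hits / totals  # value just before each hit
    pos_max = after.max(axis=1)
    neg_min = before.min(axis=1)
    # positive deviation wins magnitude ties (tolerance guards float noise)
    take_pos = np.abs(pos_max) >= np.abs(neg_min) - 1e-12
    es = np.where(take_pos, pos_max, neg_min)
    arg = np.where(take_pos, after.argmax(axis=1), before.argmin(axis=1))
    return es, arg


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: dict[str, set],
    weight_exponent: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 5000,
) -> list[GseaResult]:
    """Preranked GSEA with a gene-label permutation null.

    Sets are intersected with the ranked universe; those outside
    [min_size, max_size] are skipped. When all scores are zero the
    weighting degenerates and the unweighted (w=0) statistic is used with
    a warning.
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    ids = np.array(ranked.index)
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(ids)
    weights = np.abs(scores) ** weight_exponent
    if weights.sum() == 0:
        import warnings

        warnings.warn("all ranking scores are zero; falling back to unweighted ES")
        weight_exponent = 0.0
        weights = np.ones(n)
    id_pos = {g: i for i, g in enumerate(ids)}
    rng = np.random.default_rng(seed)

    members: dict[str, np.ndarray] = {}
    for name, genes in sets.items():
        pos = np.array(sorted(id_pos[g] for g in genes if g in id_pos), dtype=int)
        if min_size <= len(pos) <= max_size:
            members[name] = pos

    # group sets by size so one permutation block serves all sets of a size
    null_by_size: dict[int, np.ndarray] = {}
    for name, pos in members.items():
        k = len(pos)
        if k not in null_by_size:
            perm_pos = np.empty((n_perm, k), dtype=int)
            chunk = max(1, int(2e6 // max(n, 1)))
            done = 0
            while done < n_perm:
                c = min(chunk, n_perm - done)
                r = rng.random((c, n))
                part = np.argpartition(r, k - 1, axis=1)[:, :k]
                perm_pos[done : done + c] = np.sort(part, axis=1)
                done += c
            null_by_size[k] = _es_from_positions(perm_pos, weights, n)[0]

    results = []
    for name, pos in members.items():
        es_arr, arg = _es_from_positions(pos[None, :], weights, n)
        es, extremum = float(es_arr[0]), int(arg[0])
        null = null_by_size[len(pos)]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        # one-sided add-one p against the same-sign portion of the null,
        # the convention under which null p-values are ~uniform
        p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (len(same_sign) + 1)
        if es >= 0:
            leading = [ids[p_] for p_ in pos[: extremum + 1]]
        else:
            leading = [ids[p_] for p_ in pos[extremum:]]
        results.append(
            GseaResult(
                set_name=name,
                es=es,
                nes=float(nes),
                p_value=float(p),
                fdr=np.nan,
                leading_edge=leading,
                set_size=len(pos),
            )
        )
    if results:
        fdrs = bh_adjust(np.array([r.p_value for r in results]))
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results


def hypergeometric_ora(query: set, gene_set: set, universe: set) -> OraResult:
    """Exact hypergeometric over-representation: P(overlap >= k)."""
    if not query <= universe:
        raise ValueError("query genes outside the universe")
    if not gene_set <= universe:
        raise ValueError("set genes outside the universe")
    N, K, n = len(universe), len(gene_set), len(query)
    k = len(query & gene_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OraResult(
        set_name="", overlap=k, set_size=K, query_size=n, universe_size=N, p_value=p
    )


def chromosome_silencing_scan(
    contrast_tables: dict[str, pd.DataFrame],
    chromosome_sets: dict[str, set],
    weight_exponent: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """One preranked GSEA per modality against the chromosome/PAR sets.

    ``contrast_tables`` maps modality name -> contrast table (one row per
    feature of that modality's universe). Returns a tidy frame with one
    row per (modality, set): es, nes, p, fdr (BH within modality), size.
    Positive NES in a methylation modality = enriched hypermethylation;
    negative NES in transcripts/proteins = enriched downregulation.
    """
    rows = []
    for modality, table in contrast_tables.items():
        ranked = rank_by_lfc(table)
        results = gsea_preranked(
            ranked,
            chromosome_sets,
            weight_exponent=weight_exponent,
            n_perm=n_perm,
            seed=seed,
            min_size=min_size,
        )
        for r in results:
            rows.append(
                {
                    "modality": modality,
                    "set_name": r.set_name,
                    "es": r.es,
                    "nes": r.nes,
                    "p": r.p_value,
                    "fdr": r.fdr,
                    "set_size": r.set_size,
                }
            )
    return pd.DataFrame(rows)


def xlinked_fraction_summary(
    significant_features: set,
    x_set: set,
    universe: set,
) -> dict:
    """Fraction of significant features that are X-linked, with the
    hypergeometric enrichment p for that overlap.

    ``universe`` is every tested feature of the modality. An empty
    significant list yields a missing fraction.
    """
    if not (x_set & universe):
        raise ValueError("X set absent from the universe")
    sig = set(significant_features)
    n = len(sig)
    if n == 0:
        return {"k": 0, "n": 0, "fraction": np.nan, "p": np.nan}
    ora = hypergeometric_ora(sig, x_set & universe, universe)
    return {
        "k": ora.overlap,
        "n": n,
        "fraction": ora.overlap / n,
        "p": ora.p_value,
    }


def xci_panel_summary(
    table: pd.DataFrame,
    panel: list,
    fdr_max: float = 0.1,
    fc_min: float = 1.5,
) -> dict:
    """Silencing summary over a curated X-inactivation gene panel.

    n_down counts panel genes with LFC < 0 and FDR < fdr_max; the strong
    tier additionally requires |FC| > fc_min. Denominators use panel genes
    present in the tested universe.
    """
    present = [g for g in panel if g in table.index]
    if not present:
        raise ValueError("no panel genes in the tested universe")
    sub = table.loc[present]
    down = (sub["lfc"] < 0) & (sub["fdr"] < fdr_max)
    strong = down & (sub["lfc"].abs() > np.log2(fc_min))
    n = len(present)
    return {
        "n_panel_tested": n,
        "n_down": int(down.sum()),
        "n_strong_down": int(strong.sum()),
        "fraction_down": float(down.sum() / n),
        "fraction_strong_down": float(strong.sum() / n),
    }
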