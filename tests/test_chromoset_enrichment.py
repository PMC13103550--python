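import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dimorphix.chromoset_enrichment import (
    chromosome_silencing_scan,
    gsea_preranked,
    hypergeometric_ora,
    rank_by_lfc,
    xci_panel_summary,
    xlinked_fraction_summary,
)
from _oracles import gsea_es_bruteforce, hypergeom_tail_enumeration


def ranked_frame(scores, ids=None):
    ids = ids or [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame({"score": scores}, index=ids)


class TestRankByLfc:
    def test_descending_order(self):
        t = pd.DataFrame({"lfc": [2.0, 1.0, 3.0], "p": [0.1] * 3}, index=["a", "b", "c"])
        assert list(rank_by_lfc(t).index) == ["c", "a", "b"]

    def test_ties_break_by_p_then_id(self):
        t = pd.DataFrame(
            {"lfc": [1.0, 1.0, 1.0], "p": [0.5, 0.01, 0.01]}, index=["x", "z", "y"]
        )
        assert list(rank_by_lfc(t).index) == ["y", "z", "x"]

    def test_duplicate_ids_rejected(self):
        t = pd.DataFrame({"lfc": [1.0, 2.0], "p": [0.1, 0.1]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            rank_by_lfc(t)


class TestGseaEs:
    def test_top_gene_set_reaches_plus_one(self):
        ranked = ranked_frame([3.0, 2.0, 1.0, 0.5])
        (res,) = gsea_preranked(ranked, {"s": {"g0"}}, n_perm=50, seed=0, min_size=1)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g0"]

    def test_bottom_gene_set_reaches_minus_one(self):
        ranked = ranked_frame([3.0, 2.0, 1.0, 0.5])
        (res,) = gsea_preranked(ranked, {"s": {"g3"}}, n_perm=50, seed=0, min_size=1)
        assert res.es == pytest.approx(-1.0)

    def test_matches_bruteforce_running_sum(self, rng):
        """Vectorized ES equals an independent naive implementation on 200
        random (list, set) instances."""
        for _ in range(200):
            n = int(rng.integers(6, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            members = rng.choice(n, size=k, replace=False)
            ids = [f"g{i}" for i in range(n)]
            ranked = ranked_frame(list(scores), ids)
            gene_set = {ids[i] for i in members}
            (res,) = gsea_preranked(
                ranked, {"s": gene_set}, n_perm=2, seed=0, min_size=1
            )
            in_set = np.isin(np.arange(n), members)
            assert res.es == pytest.approx(
                gsea_es_bruteforce(scores, in_set), abs=1e-12
            )

    def test_singleton_set_unweighted_p_matches_enumeration(self, rng):
        """With w=0 and a single-gene set, the permutation p equals the
        exact placement probability P(ES_perm >= ES_obs)."""
        n = 12
        scores = np.sort(rng.normal(size=n))[::-1]
        ids = [f"g{i}" for i in range(n)]
        # exact null: ES for a singleton at position i (w=0)
        def es_at(i):
            in_set = np.zeros(n, bool)
            in_set[i] = True
            return gsea_es_bruteforce(scores, in_set, weight_exponent=0)

        null = np.array([es_at(i) for i in range(n)])
        pos = 2
        observed = es_at(pos)
        same_sign = null[np.sign(null) == np.sign(observed)]
        exact_p = (np.abs(same_sign) >= abs(observed)).mean()
        ranked = ranked_frame(list(scores), ids)
        (res,) = gsea_preranked(
            ranked, {"s": {ids[pos]}}, weight_exponent=0, n_perm=20000, seed=1, min_size=1
        )
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy import stats

        n = 200
        scores = np.sort(rng.normal(size=n))[::-1]
        ids = [f"g{i}" for i in range(n)]
        sets = {
            f"s{j}": set(rng.choice(ids, size=15, replace=False)) for j in range(40)
        }
        ranked = ranked_frame(list(scores), ids)
        results = gsea_preranked(ranked, sets, n_perm=500, seed=2)
        ps = [r.p_value for r in results]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_scores_fall_back_to_unweighted(self):
        ranked = ranked_frame([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="unweighted"):
            (res,) = gsea_preranked(ranked, {"s": {"g0"}}, n_perm=20, seed=0, min_size=1)
        assert np.isfinite(res.es)

    def test_empty_ranked_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gsea_preranked(ranked_frame([]), {"s": {"a"}}, n_perm=10, seed=0)


class TestHypergeometricOra:
    def test_full_overlap_small_universe(self):
        uni = set(range(10))
        res = hypergeometric_ora(set(range(5)), set(range(5)), uni)
        assert res.p_value == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_p_one(self):
        uni = set(range(10))
        res = hypergeometric_ora({0, 1}, {8, 9}, uni)
        assert res.overlap == 0 and res.p_value == pytest.approx(1.0)

    def test_partial_overlap(self):
        uni = set(range(4))
        res = hypergeometric_ora({0, 1}, {1, 2}, uni)
        assert res.p_value == pytest.approx(5 / 6, rel=1e-9)

    def test_matches_enumeration_all_small_universes(self):
        for N in range(2, 13):
            uni = set(range(N))
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        query = set(range(k)) | set(range(K, K + n - k))
                        gene_set = set(range(K))
                        if not query <= uni:
                            continue
                        res = hypergeometric_ora(query, gene_set, uni)
                        assert res.overlap == k
                        assert res.p_value == pytest.approx(
                            hypergeom_tail_enumeration(N, K, n, k), rel=1e-9
                        )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_ora({99}, {1}, {1, 2})


class TestScan:
    def test_planted_x_signal_recovered(self, small_cohort):
        """Male-contrast methylation ranking shows positive X enrichment;
        the female contrast does not."""
        from dimorphix import factorial_de, qc_preprocess
        from dimorphix.annotation_io import FeatureMatrix

        cohort = small_cohort
        vals = qc_preprocess.logit_transform(
            FeatureMatrix(values=cohort.matrices["promoter_meth"], modality="promoter_meth")
        )
        design = factorial_de.make_design(cohort.samples["sex"], cohort.samples["disease"])
        fits = factorial_de.fit_feature_models(vals, design)
        prior = factorial_de.estimate_variance_prior(fits.s2, fits.df_residual)
        tables = {
            name: factorial_de.contrast_table(fits, prior, c, name)
            for name, c in factorial_de.CONTRASTS.items()
        }
        ann = cohort.annotations["promoter_meth"]
        sets = {name: set(sub["feature_id"]) for name, sub in ann.groupby("chromosome")}
        male = chromosome_silencing_scan(
            {"promoter_meth": tables["male_SLE_vs_HC"]}, sets, n_perm=500, seed=3
        )
        female = chromosome_silencing_scan(
            {"promoter_meth": tables["female_SLE_vs_HC"]}, sets, n_perm=500, seed=3
        )
        mx = male[male.set_name == "X"].iloc[0]
        fx = female[female.set_name == "X"].iloc[0]
        assert mx.nes > 0 and mx.fdr <= 0.1
        assert fx.fdr > 0.1

    def test_skips_undersized_sets(self):
        t = pd.DataFrame(
            {"lfc": np.linspace(2, -2, 30), "p": np.full(30, 0.5)},
            index=[f"g{i}" for i in range(30)],
        )
        sets = {"big": {f"g{i}" for i in range(10)}, "tiny": {"g0", "g1"}}
        scan = chromosome_silencing_scan({"m": t}, sets, n_perm=50, seed=0, min_size=5)
        assert set(scan.set_name) == {"big"}


class TestSummaries:
    def test_xlinked_fraction_printed_ratio(self):
        universe = {f"f{i}" for i in range(36175)}
        x_set = {f"f{i}" for i in range(8000)}
        sig = {f"f{i}" for i in range(64)} | {f"f{i}" for i in range(8000, 8003)}
        out = xlinked_fraction_summary(sig, x_set, universe)
        assert out["k"] == 64 and out["n"] == 67
        assert out["fraction"] == pytest.approx(64 / 67)
        assert int(100 * out["fraction"]) == 95  # printed as a truncated percent
        assert out["p"] < 1e-30

    def test_empty_significant_list_missing_fraction(self):
        out = xlinked_fraction_summary(set(), {"a"}, {"a", "b"})
        assert np.isnan(out["fraction"])

    def test_x_absent_from_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            xlinked_fraction_summary({"a"}, {"zz"}, {"a", "b"})

    def test_xci_panel_counts(self):
        table = pd.DataFrame(
            {
                "lfc": [-1.0, -0.2, -0.7, 0.5, 0.1],
                "fdr": [0.01, 0.05, 0.2, 0.01, 0.5],
            },
            index=[f"g{i}" for i in range(5)],
        )
        out = xci_panel_summary(table, [f"g{i}" for i in range(5)])
        assert out["n_panel_tested"] == 5
        assert out["n_down"] == 2  # g0 and g1 (lfc<0, fdr<0.1)
        assert out["n_strong_down"] == 1  # only g0 passes |FC|>1.5
        assert out["fraction_down"] == pytest.approx(0.4)

    def test_empty_panel_intersection_rejected(self):
        table = pd.DataFrame({"lfc": [1.0], "fdr": [0.5]}, index=["g0"])
        with pytest.raises(ValueError, match="panel"):
            xci_panel_summary(table, ["absent"])
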