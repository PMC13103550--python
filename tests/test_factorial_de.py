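import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dimorphix.factorial_de import (
    CONTRASTS,
    VariancePrior,
    bh_adjust,
    call_significant,
    contrast_table,
    estimate_variance_prior,
    fit_feature_models,
    make_design,
    moderated_t,
    venn_partition,
)
from _oracles import bh_stepup_reference


def four_cell_design(n_per_cell=3):
    sex = pd.Series(["F"] * 2 * n_per_cell + ["M"] * 2 * n_per_cell)
    disease = pd.Series((["HC"] * n_per_cell + ["SLE"] * n_per_cell) * 2)
    return make_design(sex, disease), sex, disease


class TestFit:
    def test_exact_cell_mean_algebra(self):
        design, sex, disease = four_cell_design(2)
        means = {"F_HC": 0.0, "F_SLE": 1.0, "M_HC": 0.0, "M_SLE": 5.0}
        y = np.array(
            [[means[f"{s}_{d}"] for s, d in zip(sex, disease)]], dtype=float
        )
        fits = fit_feature_models(pd.DataFrame(y, index=["f"]), design)
        assert np.allclose(fits.beta[0], [0.0, 0.0, 1.0, 4.0])

    def test_zero_interaction_recovered(self):
        design, sex, disease = four_cell_design(2)
        means = {"F_HC": 1.0, "F_SLE": 3.0, "M_HC": 2.0, "M_SLE": 4.0}
        y = np.array([[means[f"{s}_{d}"] for s, d in zip(sex, disease)]])
        fits = fit_feature_models(pd.DataFrame(y, index=["f"]), design)
        assert fits.beta[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_match_unweighted(self, rng):
        design, *_ = four_cell_design(4)
        y = pd.DataFrame(rng.normal(size=(20, 16)))
        w = pd.DataFrame(np.full((20, 16), 2.5))
        fw = fit_feature_models(y, design, weights=w)
        fu = fit_feature_models(y, design)
        assert np.allclose(fw.beta, fu.beta)
        # weighted residual variance scales with the weights
        assert np.allclose(fw.s2, 2.5 * fu.s2)

    def test_rank_deficient_design_rejected(self):
        sex = pd.Series(["F", "F", "M", "M"])
        disease = pd.Series(["HC", "SLE", "HC", "SLE"])
        with pytest.raises(ValueError, match="rank"):
            # duplicating the sex column breaks full rank
            design = make_design(sex, disease)
            bad = np.column_stack([design, design[:, 1]])
            fit_feature_models(pd.DataFrame(np.zeros((5, 4))), bad)

    def test_missing_cell_rejected(self):
        sex = pd.Series(["F", "F", "M", "M"])
        disease = pd.Series(["HC", "SLE", "HC", "HC"])  # no male SLE
        with pytest.raises(ValueError, match="cell"):
            make_design(sex, disease)


class TestVariancePrior:
    def test_recovers_simulated_hyperparameters(self, rng):
        d0_true, s02_true, d_g = 8.0, 2.0, 10.0
        n_feat = 5000
        # sigma^2 ~ s02 * d0 / chi2_{d0}; s2 | sigma2 ~ sigma2 chi2_d / d
        sigma2 = s02_true * d0_true / rng.chisquare(d0_true, n_feat)
        s2 = sigma2 * rng.chisquare(d_g, n_feat) / d_g
        prior = estimate_variance_prior(s2, d_g)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s02 == pytest.approx(s02_true, rel=0.15)

    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 1.7)
        prior = estimate_variance_prior(s2, 10.0)
        assert np.isinf(prior.d0)
        assert prior.s02 == pytest.approx(1.7, rel=1e-6)

    def test_prior_df_positive(self, rng):
        s2 = rng.chisquare(5, 200) / 5
        prior = estimate_variance_prior(s2, 5.0)
        assert prior.d0 > 0


class TestModeratedT:
    def make_fits(self, rng, n_feat=200, n=16):
        design, *_ = four_cell_design(n // 4)
        y = pd.DataFrame(rng.normal(size=(n_feat, n)))
        return fit_feature_models(y, design), design

    def test_d0_zero_equals_ordinary_t(self, rng):
        fits, design = self.make_fits(rng)
        prior = VariancePrior(d0=0.0, s02=1.0)
        c = CONTRASTS["interaction"]
        t_mod, p_mod = moderated_t(fits, prior, c)
        # ordinary t computed independently
        var_factor = c @ np.linalg.inv(design.T @ design) @ c
        t_ord = (fits.beta @ c) / np.sqrt(fits.s2 * var_factor)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), fits.df_residual)
        assert np.allclose(t_mod, t_ord, rtol=1e-12)
        assert np.allclose(p_mod, p_ord, rtol=1e-10)

    def test_d0_infinite_uses_prior_variance(self, rng):
        fits, design = self.make_fits(rng)
        prior = VariancePrior(d0=np.inf, s02=3.0)
        c = CONTRASTS["interaction"]
        t_mod, _ = moderated_t(fits, prior, c)
        var_factor = c @ np.linalg.inv(design.T @ design) @ c
        expected = (fits.beta @ c) / np.sqrt(3.0 * var_factor)
        assert np.allclose(t_mod, expected)

    def test_null_p_values_uniform(self, rng):
        fits, design = self.make_fits(rng, n_feat=5000, n=16)
        prior = estimate_variance_prior(fits.s2, fits.df_residual)
        _, p = moderated_t(fits, prior, CONTRASTS["interaction"])
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.03, 0.4], [0.06, 0.4]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert np.allclose(bh_adjust(np.array(p)), expected)

    def test_matches_reference_loop_and_statsmodels(self, rng):
        p = rng.random(500)
        q = bh_adjust(p)
        assert np.allclose(q, bh_stepup_reference(p))
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_q_at_least_p(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestSignificance:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [(0.60, 0.05, True), (0.58, 0.01, False), (2.0, 0.2, False)],
    )
    def test_fc_and_fdr_thresholds(self, lfc, fdr, expected):
        table = pd.DataFrame({"lfc": [lfc], "fdr": [fdr]})
        assert bool(call_significant(table).iloc[0]) is expected


class TestVenn:
    def make(self, sig, lfc):
        return pd.DataFrame(
            {"significant": sig, "lfc": lfc}, index=[f"f{i}" for i in range(len(sig))]
        )

    def test_disjoint_sets_no_shared(self):
        f = self.make([True, False], [1.0, 1.0])
        m = self.make([False, True], [1.0, 1.0])
        v = venn_partition(f, m)
        assert v["shared_up"] == 0 and v["female_only_up"] == 1 and v["male_only_up"] == 1

    def test_identical_sets_all_shared(self):
        f = self.make([True, True], [1.0, -1.0])
        m = self.make([True, True], [2.0, -0.5])
        v = venn_partition(f, m)
        assert v["shared_up"] == 1 and v["shared_down"] == 1 and v["discordant"] == 0

    def test_discordant_direction_counted(self):
        f = self.make([True], [1.0])
        m = self.make([True], [-1.0])
        assert venn_partition(f, m)["discordant"] == 1

    def test_partition_is_exhaustive(self, rng):
        n = 50
        f = self.make(rng.random(n) < 0.4, rng.normal(size=n))
        m = self.make(rng.random(n) < 0.4, rng.normal(size=n))
        v = venn_partition(f, m)
        n_sig_any = int((f["significant"] | m["significant"]).sum())
        assert sum(v.values()) == n_sig_any

    def test_mismatched_universe_rejected(self):
        f = self.make([True], [1.0])
        m = self.make([True, False], [1.0, 1.0])
        with pytest.raises(ValueError, match="universe"):
            venn_partition(f, m)


class TestContrastTable:
    def test_interaction_recovery_on_planted_cohort(self, small_cohort):
        """The moderated interaction estimate recovers the planted XIST
        effect on one noisy cohort within sampling error."""
        from dimorphix import qc_preprocess
        from dimorphix.annotation_io import FeatureMatrix

        cohort = small_cohort
        counts = FeatureMatrix(
            values=cohort.matrices["rna_counts"], modality="rna_counts"
        )
        logcpm = qc_preprocess.log_cpm(counts)
        design = make_design(cohort.samples["sex"], cohort.samples["disease"])
        fits = fit_feature_models(logcpm.values, design)
        prior = estimate_variance_prior(fits.s2, fits.df_residual)
        table = contrast_table(fits, prior, CONTRASTS["interaction"], "interaction")
        est = table.loc["XIST", "lfc"]
        # single replicate: mixture sampling alone has sd ~ 0.7
        assert est == pytest.approx(cohort.spec.xist_interaction_lfc, abs=2.5)
        assert table.loc["XIST", "fdr"] < 0.05
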