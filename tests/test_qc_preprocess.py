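import numpy as np
import pandas as pd
import pytest

from dimorphix.annotation_io import FeatureMatrix
from dimorphix.qc_preprocess import (
    LodTable,
    exclude_low_expression_samples,
    filter_low_counts,
    filter_npx_by_lod,
    log_cpm,
    quantile_normalize,
    sex_qc_read_depth,
    summarize_methylation_regions,
    voom_weights,
)
from dimorphix.synthetic_cohort import simulate_read_depths


def npx_matrix(values, assays=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    assays = assays or [f"a{i}" for i in range(arr.shape[0])]
    cols = [f"s{i}" for i in range(arr.shape[1])]
    return FeatureMatrix(
        values=pd.DataFrame(arr, index=assays, columns=cols), modality="protein_npx"
    )


class TestLodFilter:
    @pytest.mark.parametrize(
        "n_above,n_total,kept",
        [(8, 10, True), (7, 10, False), (75, 100, False), (76, 100, True)],
    )
    def test_strictly_more_than_threshold(self, n_above, n_total, kept):
        vals = [2.0] * n_above + [0.0] * (n_total - n_above)
        mat = npx_matrix([vals])
        lod = LodTable(lod=pd.Series({"a0": 1.0}))
        out = filter_npx_by_lod(mat, lod)
        assert ("a0" in out.values.index) is kept

    def test_fail_flags_blanked_before_filtering(self):
        mat = npx_matrix([[2.0] * 10])
        flags = pd.DataFrame(
            [["FAIL"] * 3 + ["PASS"] * 7], index=["a0"], columns=mat.values.columns
        )
        out = filter_npx_by_lod(mat, LodTable(lod=pd.Series({"a0": 1.0})), flags=flags)
        # 7/10 above LOD after blanking -> dropped
        assert "a0" not in out.values.index

    def test_missing_lod_is_error(self):
        mat = npx_matrix([[2.0] * 4])
        with pytest.raises(ValueError, match="without LOD"):
            filter_npx_by_lod(mat, LodTable(lod=pd.Series({"other": 1.0})))

    def test_idempotent(self, rng):
        mat = npx_matrix(rng.normal(2, 1, (30, 20)))
        lod = LodTable(lod=pd.Series(1.5, index=mat.values.index))
        once = filter_npx_by_lod(mat, lod)
        twice = filter_npx_by_lod(once, lod)
        assert once.values.equals(twice.values)


class TestSampleExclusion:
    def test_identical_samples_none_excluded(self):
        mat = npx_matrix(np.full((5, 6), 3.0))
        assert exclude_low_expression_samples(mat) == []

    def test_extreme_low_sample_excluded(self, rng):
        arr = rng.normal(3, 0.1, (50, 20))
        means = arr.mean(axis=0)
        sd = means.std(ddof=1)
        arr[:, 0] -= 10 * sd * 20  # push sample 0 far below the cohort
        out = exclude_low_expression_samples(npx_matrix(arr))
        assert out == ["s0"]

    def test_boundary_sample_retained_strict_inequality(self):
        # one low sample among n=16 equal samples sits at exactly
        # mean - k sd of the sample means when k = (n-1)/sqrt(n) = 3.75
        arr = np.full((5, 16), 2.0)
        arr[:, 0] = 1.0
        mat = npx_matrix(arr)
        assert exclude_low_expression_samples(mat, k_sd=3.75) == []
        assert exclude_low_expression_samples(mat, k_sd=3.74) == ["s0"]


class TestCountFilter:
    def make(self, arr, groups):
        mat = FeatureMatrix(
            values=pd.DataFrame(
                np.asarray(arr, dtype=float),
                index=[f"g{i}" for i in range(len(arr))],
                columns=[f"s{i}" for i in range(len(arr[0]))],
            ),
            modality="rna_counts",
        )
        return mat, pd.Series(groups, index=mat.values.columns)

    def test_uniform_counts_at_cutoff_kept(self):
        # library sizes 1e6 via a filler feature; counts 10 -> CPM 10 = cutoff
        filler = [1e6 - 10] * 6
        mat, groups = self.make([[10] * 6, filler], ["a", "a", "a", "b", "b", "b"])
        kept = filter_low_counts(mat, groups, min_count=10)
        assert "g0" in kept

    def test_all_zero_feature_dropped(self):
        mat, groups = self.make([[0] * 6, [100] * 6], ["a"] * 3 + ["b"] * 3)
        assert "g0" not in filter_low_counts(mat, groups)

    def test_single_sample_spike_dropped(self):
        filler = [1e6] * 6
        mat, groups = self.make(
            [[100, 0, 0, 0, 0, 0], filler], ["a", "a", "a", "b", "b", "b"]
        )
        assert "g0" not in filter_low_counts(mat, groups)

    def test_idempotent(self, rng):
        arr = rng.poisson(30, (40, 12))
        mat, groups = self.make(arr, ["a"] * 6 + ["b"] * 6)
        kept = filter_low_counts(mat, groups)
        sub = FeatureMatrix(values=mat.values.loc[kept], modality="rna_counts")
        assert filter_low_counts(sub, groups) == kept


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_mean_of_order_statistics(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_columns_share_sorted_multiset(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_projection(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        once = quantile_normalize(df)
        assert np.allclose(quantile_normalize(once), once)

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0]})
        assert quantile_normalize(df).equals(df)


class TestLogCpm:
    def test_formula(self):
        counts = FeatureMatrix(
            values=pd.DataFrame({"s": [100.0, 0.0, 999900.0]}, index=["g1", "g2", "g3"]),
            modality="rna_counts",
        )
        out = log_cpm(counts).values["s"]
        assert out["g1"] == pytest.approx(np.log2(100.5 / 1000001 * 1e6), abs=1e-9)
        assert out["g1"] == pytest.approx(6.6511, abs=1e-3)
        assert out["g2"] == pytest.approx(-0.99999, abs=1e-3)

    def test_equal_inputs_equal_outputs(self):
        counts = FeatureMatrix(
            values=pd.DataFrame(np.full((3, 4), 50.0)), modality="rna_counts"
        )
        out = log_cpm(counts).values.to_numpy()
        assert np.allclose(out, out[0, 0])


class TestVoomWeights:
    def test_homoscedastic_weights_nearly_constant(self, rng):
        y = FeatureMatrix(
            values=pd.DataFrame(5 + rng.normal(0, 1, (300, 40))),
            modality="rna_logexpr",
        )
        design = np.ones((40, 1))
        w = voom_weights(y, design).to_numpy()
        assert (w > 0).all()
        assert w.std() / w.mean() < 0.2

    def test_weights_track_planted_trend(self, rng):
        n_feat, n_samp = 400, 40
        means = np.linspace(2, 10, n_feat)
        sds = np.linspace(2.0, 0.3, n_feat)  # variance decreasing in mean
        y = means[:, None] + rng.normal(0, 1, (n_feat, n_samp)) * sds[:, None]
        mat = FeatureMatrix(values=pd.DataFrame(y), modality="rna_logexpr")
        w = voom_weights(mat, np.ones((n_samp, 1))).to_numpy()[:, 0]
        # weights should increase with mean expression
        lo, hi = w[:100].mean(), w[-100:].mean()
        assert hi > 2 * lo

    def test_few_features_fall_back_to_unit_weights(self, rng):
        mat = FeatureMatrix(
            values=pd.DataFrame(rng.normal(size=(10, 8))), modality="rna_logexpr"
        )
        with pytest.warns(UserWarning, match="unit weights"):
            w = voom_weights(mat, np.ones((8, 1)))
        assert (w.to_numpy() == 1).all()


class TestRegionSummaries:
    def setup_method(self):
        self.sites = pd.DataFrame(
            {"chromosome": ["1", "1", "1"], "position": [10, 20, 300]}
        )
        self.meth = pd.DataFrame(
            [[0.4, 0.4], [0.2, 0.6], [0.9, 0.1]], columns=["s1", "s2"]
        )

    def test_mean_within_region(self):
        regions = pd.DataFrame(
            {"gene_id": ["r1"], "chromosome": ["1"], "start": [0], "end": [25]}
        )
        out = summarize_methylation_regions(self.meth, self.sites, regions)
        assert out.values.loc["r1", "s1"] == pytest.approx(0.3)
        assert out.values.loc["r1", "s2"] == pytest.approx(0.5)

    def test_single_site_region(self):
        regions = pd.DataFrame(
            {"gene_id": ["r1"], "chromosome": ["1"], "start": [250], "end": [400]}
        )
        out = summarize_methylation_regions(self.meth, self.sites, regions)
        assert out.values.loc["r1", "s1"] == pytest.approx(0.9)

    def test_empty_region_missing(self):
        regions = pd.DataFrame(
            {"gene_id": ["r1"], "chromosome": ["1"], "start": [1000], "end": [2000]}
        )
        out = summarize_methylation_regions(self.meth, self.sites, regions)
        assert out.values.loc["r1"].isna().all()

    def test_unsorted_sites_rejected(self):
        sites = pd.DataFrame({"chromosome": ["1", "1"], "position": [20, 10]})
        meth = self.meth.iloc[:2]
        regions = pd.DataFrame(
            {"gene_id": ["r"], "chromosome": ["1"], "start": [0], "end": [30]}
        )
        with pytest.raises(ValueError, match="sorted"):
            summarize_methylation_regions(meth, sites, regions)


class TestSexQc:
    def make_depths(self, x_ratio, sex="M"):
        depths = pd.DataFrame(
            {"1": [30.0], "2": [30.0], "X": [30.0 * x_ratio]}, index=["s"]
        )
        return depths, pd.Series({"s": sex})

    @pytest.mark.parametrize(
        "ratio,sex,anomalous",
        [(0.5, "M", False), (1.0, "M", True), (0.5, "F", True), (1.0, "F", False)],
    )
    def test_expected_ratios(self, ratio, sex, anomalous):
        depths, reported = self.make_depths(ratio, sex)
        (report,) = sex_qc_read_depth(depths, reported)
        assert report.anomalous is anomalous

    def test_planted_aneuploidies_flagged_noise_free(self, zero_noise_cohort):
        cohort = zero_noise_cohort
        depths = simulate_read_depths(cohort.ground_truth)
        reports = sex_qc_read_depth(depths, cohort.samples["sex"])
        flagged = {r.sample_id for r in reports if r.anomalous}
        planted = set(
            cohort.ground_truth.karyotype[
                cohort.ground_truth.karyotype.isin(["XXY", "XO"])
            ].index
        )
        assert flagged == planted
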