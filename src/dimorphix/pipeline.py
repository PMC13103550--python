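"""End-to-end orchestration: simulate -> QC -> DE -> classify -> enrich ->
deconvolve -> screen, from one config, with a JSON run manifest.

Every stage writes TSV artifacts into the configured output directory and
records its input/output feature counts in the manifest; a rerun with the
same config and seed is bit-identical. The config carries every constant
the analysis uses (thresholds, window sizes, permutation counts, seeds,
toggles); see :class:`PipelineConfig` for defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (
    annotation_io,
    chromoset_enrichment,
    cohort_stats,
    deconvolution,
    factorial_de,
    qc_preprocess,
    synthetic_cohort,
    xist_bimodality,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

MODALITY_STAGES = ("promoter_meth", "gene_meth", "rna", "protein_npx")


@dataclass
class PipelineConfig:
    outdir: str = "dimorphix_out"
    seed: int = 0

    # significance thresholds
    fdr_max: float = 0.1
    fc_min: float = 1.5

    # QC constants
    lod_min_frac: float = 0.75
    sample_exclusion_sd: float = 4.0
    min_count: float = 10.0
    sex_qc_tol: float = 0.25

    # promoter window (annotation stage)
    promoter_upstream: int = 2000
    promoter_downstream: int = 200

    # enrichment / dip-test simulation sizes
    n_perm: int = 1000
    n_mc: int = 10000

    # toggles
    use_voom_weights: bool = True
    meth_scale: str = "logit"  # or "log2_fraction"
    ifn_rule: str = "zscore_mean"

    # synthetic cohort overrides (merged into CohortSpec)
    cohort: dict = field(default_factory=dict)

    def cohort_spec(self) -> synthetic_cohort.CohortSpec:
        params = dict(self.cohort)
        params.setdefault("seed", self.seed)
        return synthetic_cohort.CohortSpec(**params)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _digest(path: pathlib.Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _meth_analysis_values(matrix, scale: str) -> pd.DataFrame:
    from .annotation_io import FeatureMatrix

    if scale == "logit":
        return qc_preprocess.logit_transform(matrix)
    if scale == "log2_fraction":
        return np.log2(matrix.values.clip(lower=1e-4))
    raise ValueError(f"unknown methylation scale {scale!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the manifest dict."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": dataclasses.asdict(config)}
    written: list[pathlib.Path] = []

    def save(frame: pd.DataFrame, name: str, index_label="feature_id"):
        path = out / name
        frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        written.append(path)
        return path

    # ---- stage 1: simulate --------------------------------------------
    spec = config.cohort_spec()
    cohort = synthetic_cohort.simulate_cohort(spec)
    samples = cohort.samples
    manifest["stages"]["simulate"] = {
        "n_samples": int(len(samples)),
        "features": {k: int(v.shape[0]) for k, v in cohort.matrices.items()},
    }

    # ---- stage 2: sex QC on chromosome read depths ---------------------
    depths = synthetic_cohort.simulate_read_depths(cohort.ground_truth, seed=config.seed)
    reports = qc_preprocess.sex_qc_read_depth(
        depths, samples["sex"], tol=config.sex_qc_tol
    )
    qc = pd.DataFrame(
        [
            {"sample_id": r.sample_id, "ratio": r.ratio, "expected": r.expected, "anomalous": r.anomalous}
            for r in reports
        ]
    ).set_index("sample_id")
    save(qc, "sex_qc.tsv", index_label="sample_id")
    keep = qc.index[~qc["anomalous"]]
    samples = samples.loc[keep]
    manifest["stages"]["sex_qc"] = {
        "samples_in": int(len(qc)),
        "samples_kept": int(len(keep)),
        "samples_flagged": int(qc["anomalous"].sum()),
    }

    # ---- stage 3: protein QC ------------------------------------------
    npx = annotation_io.FeatureMatrix(
        values=cohort.matrices["protein_npx"][keep], modality="protein_npx"
    )
    lodtab = qc_preprocess.LodTable(lod=cohort.lod)
    npx_filtered = qc_preprocess.filter_npx_by_lod(
        npx, lodtab, flags=cohort.qc_flags[keep], min_frac=config.lod_min_frac
    )
    excluded = qc_preprocess.exclude_low_expression_samples(
        npx_filtered, k_sd=config.sample_exclusion_sd
    )
    prot_samples = [s for s in keep if s not in set(excluded)]
    npx_values = npx_filtered.values[prot_samples]
    # QC-blanked measurements are sparse after filtering; impute with the
    # assay median so the factorial fits see complete data
    npx_values = npx_values.mask(
        npx_values.isna(), npx_values.median(axis=1), axis=0
    )
    manifest["stages"]["protein_qc"] = {
        "assays_in": int(npx.values.shape[0]),
        "assays_kept": int(npx_values.shape[0]),
        "assays_filtered": int(npx.values.shape[0] - npx_values.shape[0]),
        "samples_excluded": len(excluded),
    }

    # ---- stage 4: RNA preprocessing -----------------------------------
    rna_counts = annotation_io.FeatureMatrix(
        values=cohort.matrices["rna_counts"][keep], modality="rna_counts"
    )
    group = samples["sex"] + "_" + samples["disease"]
    kept_genes = qc_preprocess.filter_low_counts(
        rna_counts, group, min_count=config.min_count
    )
    manifest["stages"]["rna_filter"] = {
        "features_in": int(rna_counts.values.shape[0]),
        "features_kept": len(kept_genes),
        "features_filtered": int(rna_counts.values.shape[0] - len(kept_genes)),
    }
    rna_counts = annotation_io.FeatureMatrix(
        values=rna_counts.values.loc[kept_genes], modality="rna_counts"
    )
    logcpm = qc_preprocess.log_cpm(rna_counts)
    logcpm_qn = qc_preprocess.quantile_normalize(logcpm.values)
    rna_logexpr = annotation_io.FeatureMatrix(values=logcpm_qn, modality="rna_logexpr")

    # ---- stage 5: factorial DE per modality ---------------------------
    design = factorial_de.make_design(samples["sex"], samples["disease"])
    weights = None
    if config.use_voom_weights:
        weights = qc_preprocess.voom_weights(rna_logexpr, design)

    analysis_values = {
        "promoter_meth": _meth_analysis_values(
            annotation_io.FeatureMatrix(
                values=cohort.matrices["promoter_meth"][keep], modality="promoter_meth"
            ),
            config.meth_scale,
        ),
        "gene_meth": _meth_analysis_values(
            annotation_io.FeatureMatrix(
                values=cohort.matrices["gene_meth"][keep], modality="gene_meth"
            ),
            config.meth_scale,
        ),
        "rna": rna_logexpr.values,
        "protein_npx": npx_values,
    }
    contrast_tables: dict[str, dict[str, pd.DataFrame]] = {}
    venns: dict[str, dict] = {}
    for modality, values in analysis_values.items():
        if modality == "protein_npx":
            dsg = factorial_de.make_design(
                samples.loc[prot_samples, "sex"], samples.loc[prot_samples, "disease"]
            )
        else:
            dsg = design
        w = weights if (modality == "rna" and weights is not None) else None
        fits = factorial_de.fit_feature_models(values, dsg, weights=w)
        prior = factorial_de.estimate_variance_prior(fits.s2, fits.df_residual)
        tables = {}
        for cname, cvec in factorial_de.CONTRASTS.items():
            tbl = factorial_de.contrast_table(
                fits, prior, cvec, cname, fdr_max=config.fdr_max, fc_min=config.fc_min
            )
            tables[cname] = tbl
            save(tbl, f"de_{modality}_{cname}.tsv")
        contrast_tables[modality] = tables
        venns[modality] = factorial_de.venn_partition(
            tables["female_SLE_vs_HC"], tables["male_SLE_vs_HC"]
        )
    manifest["stages"]["factorial_de"] = {
        "venn": venns,
        "significant": {
            m: {c: int(t["significant"].sum()) for c, t in tabs.items()}
            for m, tabs in contrast_tables.items()
        },
    }

    # ---- stage 6: XIST bimodality and classification -------------------
    msle = samples.index[(samples["sex"] == "M") & (samples["disease"] == "SLE")]
    fsle = samples.index[(samples["sex"] == "F") & (samples["disease"] == "SLE")]
    rel = xist_bimodality.normalize_qpcr(
        samples["ct_xist"],
        samples["ct_gapdh"],
        samples["sex"],
        samples["disease"] == "HC",
    )
    log_rel = np.log2(rel)
    xist_rna = rna_logexpr.values.loc["XIST"] if "XIST" in rna_logexpr.values.index else None
    rng_null = np.random.default_rng(config.seed)
    dip_rows = []
    for label, vals in (
        ("male_sle_qpcr", log_rel[msle].dropna()),
        ("male_sle_rnaseq", xist_rna[msle] if xist_rna is not None else None),
        ("female_sle_rnaseq", xist_rna[fsle] if xist_rna is not None else None),
    ):
        if vals is None or len(vals) < 4:
            continue
        res = xist_bimodality.dip_test(
            np.asarray(vals, dtype=float), n_mc=config.n_mc, seed=config.seed
        )
        dip_rows.append(
            {"series": label, "dip": res.statistic, "p": res.p_value, "n": res.n}
        )
    save(pd.DataFrame(dip_rows).set_index("series"), "dip_tests.tsv", index_label="series")

    classification = xist_bimodality.classify_xist(
        log_rel.reindex(msle), rnaseq=xist_rna.reindex(msle) if xist_rna is not None else None
    )
    cls = pd.DataFrame(
        {"label": classification.labels, "source": classification.sources}
    )
    save(cls, "xist_classification.tsv", index_label="sample_id")
    lev_w, lev_p = xist_bimodality.levene_test(
        xist_rna[samples.index[samples["sex"] == "F"]],
        samples.loc[samples["sex"] == "F", "disease"],
    )
    manifest["stages"]["xist_classification"] = {
        "threshold": classification.threshold,
        "n_high": int((cls["label"] == "high").sum()),
        "n_low": int((cls["label"] == "low").sum()),
        "n_rnaseq_fallback": int((cls["source"] == "rnaseq").sum()),
        "female_xist_levene": {"w": lev_w, "p": lev_p},
    }

    # ---- stage 7: subgroup DE (XIST-high / XIST-low vs male HC) --------
    male_group = pd.Series("none", index=samples.index, dtype=object)
    male_group[(samples["sex"] == "M") & (samples["disease"] == "HC")] = "M_HC"
    male_group[msle] = cls["label"].map({"high": "M_high", "low": "M_low"})
    male_samples = samples.index[male_group != "none"]
    levels = ["M_HC", "M_low", "M_high"]
    subgroup_contrasts = {
        "xist_high_vs_HC": np.array([-1.0, 0.0, 1.0]),
        "xist_low_vs_HC": np.array([-1.0, 1.0, 0.0]),
        "xist_high_vs_low": np.array([0.0, -1.0, 1.0]),
    }
    subgroup_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for modality, values in analysis_values.items():
        cols = [s for s in male_samples if s in values.columns]
        dsg = factorial_de.make_group_design(male_group.loc[cols], levels)
        fits = factorial_de.fit_feature_models(values[cols], dsg)
        fits.design_columns = tuple(levels)
        prior = factorial_de.estimate_variance_prior(fits.s2, fits.df_residual)
        tabs = {}
        for cname, cvec in subgroup_contrasts.items():
            tbl = factorial_de.contrast_table(
                fits, prior, cvec, cname, fdr_max=config.fdr_max, fc_min=config.fc_min
            )
            tabs[cname] = tbl
            save(tbl, f"de_{modality}_{cname}.tsv")
        subgroup_tables[modality] = tabs
    manifest["stages"]["subgroup_de"] = {
        m: {c: int(t["significant"].sum()) for c, t in tabs.items()}
        for m, tabs in subgroup_tables.items()
    }

    # ---- stage 8: chromosome-level enrichment --------------------------
    chrom_sets = {
        modality: {
            name: set(sub["feature_id"])
            for name, sub in ann.groupby("chromosome")
        }
        for modality, ann in cohort.annotations.items()
    }
    scan_rows = []
    for modality in ("promoter_meth", "gene_meth", "rna", "protein_npx"):
        ann_key = "rna" if modality == "rna" else modality
        sets = chrom_sets[ann_key]
        group_tables = {
            "female": contrast_tables[modality]["female_SLE_vs_HC"],
            "xist_high": subgroup_tables[modality]["xist_high_vs_HC"],
            "xist_low": subgroup_tables[modality]["xist_low_vs_HC"],
        }
        for gname, tbl in group_tables.items():
            scan = chromoset_enrichment.chromosome_silencing_scan(
                {modality: tbl}, sets, n_perm=config.n_perm, seed=config.seed
            )
            scan["group"] = gname
            scan_rows.append(scan)
    scan_all = pd.concat(scan_rows, ignore_index=True)
    save(scan_all, "chromosome_scan.tsv", index_label="row")
    x_scan = scan_all[scan_all["set_name"] == "X"]
    manifest["stages"]["chromosome_scan"] = {
        "n_rows": int(len(scan_all)),
        "x_hits": int(((x_scan["fdr"] <= config.fdr_max)).sum()),
    }

    # ---- stage 9: deconvolution benchmark ------------------------------
    tpm = deconvolution.tpm_normalize(
        cohort.matrices["rna_counts"][keep], cohort.gene_lengths
    )
    true_ref = deconvolution.ReferenceProfile(
        values=cohort.reference_profile, name="generating"
    )
    rng = np.random.default_rng(config.seed)
    perturbed = deconvolution.ReferenceProfile(
        values=cohort.reference_profile
        * rng.lognormal(0.0, 1.0, cohort.reference_profile.shape),
        name="perturbed",
    )
    estimates = []
    for ref in (true_ref, perturbed):
        for method_name, method in deconvolution.METHODS.items():
            estimates.append(method(tpm, ref))
    bench = deconvolution.benchmark_deconvolution(estimates, cohort.flow.loc[keep])
    save(bench.correlations, "deconvolution_benchmark.tsv", index_label="row")
    best = dict(zip(("reference", "method"), bench.selected))
    selected_props = next(
        e.proportions
        for e in estimates
        if (e.reference, e.method) == bench.selected
    )
    save(selected_props, "cell_proportions.tsv", index_label="sample_id")
    manifest["stages"]["deconvolution"] = {"selected": best, "score": bench.score}

    # ---- stage 10: clinical screens and correlations -------------------
    numeric_vars = [
        c for c in samples.columns
        if c in synthetic_cohort.NAMED_NUMERIC or c.startswith("num_var_")
    ]
    categorical_vars = [
        c for c in samples.columns if c == "apl_status" or c.startswith("cat_var_")
    ]
    high_m = cls.index[cls["label"] == "high"]
    low_m = cls.index[cls["label"] == "low"]
    groupings = {
        "xist_high_vs_female_sle": (
            samples.index.isin(high_m),
            samples.index.isin(fsle),
        ),
        "xist_low_vs_female_sle": (
            samples.index.isin(low_m),
            samples.index.isin(fsle),
        ),
        "xist_high_vs_low": (
            samples.index.isin(high_m),
            samples.index.isin(low_m),
        ),
    }
    screen = cohort_stats.clinical_screen(
        samples, groupings, numeric_vars, categorical_vars
    )
    save(screen, "clinical_screen.tsv", index_label="row")

    sle_samples = samples.index[samples["disease"] == "SLE"]
    xist_for_corr = xist_rna.reindex(sle_samples)
    corr = cohort_stats.correlate_features_with_covariates(
        xist_for_corr,
        samples.loc[sle_samples, numeric_vars],
        stratify_by=samples.loc[sle_samples, "sex"],
    )
    pooled = cohort_stats.correlate_features_with_covariates(
        xist_for_corr, samples.loc[sle_samples, numeric_vars]
    )
    save(pd.concat([corr, pooled], ignore_index=True), "xist_correlations.tsv", index_label="row")

    ifn = cohort_stats.ifn_signature(rna_logexpr.values, rule=config.ifn_rule)
    ifn_rows = []
    for s in ("F", "M"):
        idx = sle_samples[samples.loc[sle_samples, "sex"] == s]
        rho, p = cohort_stats.spearman_corr(xist_rna.reindex(idx), ifn.reindex(idx))
        ifn_rows.append({"sex": s, "rho": rho, "p": p, "n": len(idx)})
    save(pd.DataFrame(ifn_rows).set_index("sex"), "xist_ifn_correlation.tsv", index_label="sex")
    manifest["stages"]["clinical"] = {
        "n_screen_rows": int(len(screen)),
        "n_correlation_rows": int(len(corr) + len(pooled)),
    }

    # ---- manifest ------------------------------------------------------
    manifest["artifacts"] = {p.name: _digest(p) for p in sorted(written)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(written), out)
    return manifest
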