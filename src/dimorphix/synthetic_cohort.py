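"""Synthetic multi-omic cohort generator with planted ground truth.

Emulates the statistical structure of a four-cell sex-by-disease cohort
(female SLE, female HC, male SLE, male HC) across four molecular layers:

* RNA-seq counts: negative-binomial around per-gene log-normal baselines,
  log-normal library sizes, an XIST-like transcript that is high in all
  females, low in healthy males, and bimodal in male SLE (a two-component
  mixture with weight ``pi_high`` on the elevated mode, the modes separated
  by ``mode_separation_sd`` within-mode standard deviations), a shared
  interferon-module upregulation in SLE of both sexes, and a modest
  downregulation of a fraction of X-linked transcripts in male SLE only.
* Promoter and gene methylation: logit-normal fractions in [0, 1]; a
  planted hypermethylation shift ``delta_meth`` (log2-odds units) applied
  to a fraction ``f_x_meth`` of X-linked features in male SLE only, plus a
  small shared SLE hypomethylation pair mirroring interferon-locus
  activation.
* Protein NPX: Gaussian log2-scale abundances with per-assay limits of
  detection, sparse X-chromosome coverage, and shared/sex-specific
  disease effects.
* Sample metadata: qPCR Ct values calibrated linearly to the latent XIST
  log-expression (with a configurable number of male SLE samples missing
  qPCR), flow-cytometry proportions for four gates, clinical variables
  as noisy monotone transforms of latent disease activity and XIST class,
  and karyotypes (XX/XY plus optional XXY/XO anomalies) driving the
  chromosome read-depth table.

A subset of genes is generated as an explicit cell-type mixture from an
emitted reference profile so deconvolution has recoverable structure; the
neutrophil fraction co-varies negatively with XIST in females only.

Ground truth (true per-contrast effects, latent XIST classes, true cell
proportions, karyotypes, expected cell means) is returned for tests and is
never consumed by analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "GroundTruth", "CohortData", "simulate_cohort", "simulate_read_depths"]

CELL_TYPES = ("B", "NK", "T4", "T8", "Mono", "Neutro")
FLOW_GATES = ("B", "NK", "T4", "T8")
IFN_GENES = ("MX1", "OAS3", "LY6E", "USP18", "IFI44", "DDX60")

NAMED_NUMERIC = (
    "sledai_2k",
    "igg_serum",
    "alk_phos",
    "neutrophil_count",
    "t_cell_count",
    "bun",
    "eq5d_mobility",
    "disease_duration",
)


@dataclass
class CohortSpec:
    """Generator parameters; the defaults are the study conditions."""

    # cohort cell sizes
    n_f_sle: int = 679
    n_f_hc: int = 77
    n_m_sle: int = 41
    n_m_hc: int = 7

    # feature counts and chromosome composition
    n_rna: int = 5000
    n_promoter: int = 5000
    n_gene_meth: int = 5000
    n_protein: int = 2434
    n_protein_x: int = 66
    x_frac: float = 0.05
    y_frac: float = 0.01
    par_frac: float = 0.002

    # planted effects
    xist_interaction_lfc: float = 4.7
    xist_female_sle_lfc: float = 0.12
    xist_female_sle_sd: float = 0.4  # extra female-SLE XIST variability
    pi_high: float = 0.54
    mode_separation_sd: float = 6.0
    xist_male_baseline_logcpm: float = 3.0
    xist_female_baseline_logcpm: float = 9.0
    x_down_lfc: float = -0.4
    f_x_rna_down: float = 0.5
    ifn_lfc: float = 1.2
    n_ifn_extra: int = 44
    delta_meth: float = 1.5
    f_x_meth: float = 0.8
    n_shared_hypo_meth: int = 2
    shared_hypo_delta: float = -1.0
    n_protein_shared_up: int = 33
    n_protein_shared_down: int = 3
    n_protein_female_only: int = 223
    n_protein_male_only: int = 56
    protein_effect: float = 1.0

    # noise
    nb_dispersion: float = 0.05
    libsize_cv: float = 0.3
    libsize_mean: float = 1e6
    meth_logit_sd: float = 0.5
    npx_sd: float = 0.6
    zero_noise: bool = False

    # qPCR calibration (Ct = intercept - slope * log2 expression + noise)
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 30.0
    ct_noise_sd: float = 0.15
    n_missing_qpcr: int = 3

    # protein panel LOD structure
    lod_margin: float = 2.0
    frac_low_expressed: float = 0.08
    frac_fail_flags: float = 0.005

    # deconvolution structure
    n_marker_genes: int = 300
    dirichlet_alpha: tuple = (2.0, 2.0, 6.0, 3.0, 3.0, 22.0)
    neutro_xist_coupling: float = 0.3
    flow_noise_sd: float = 0.01

    # karyotype anomalies
    n_xxy: int = 1
    n_xo: int = 1

    # clinical table
    n_numeric_clinical: int = 95
    n_categorical_clinical: int = 31

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_f_sle, self.n_f_hc, self.n_m_sle, self.n_m_hc) < 1:
            raise ValueError("every cohort cell needs at least one sample")
        if not 0 < self.pi_high < 1:
            raise ValueError("pi_high must lie in (0, 1)")
        if not self.mode_separation_sd > 0:
            raise ValueError("mode separation must be positive")
        if not 0 <= self.f_x_meth <= 1:
            raise ValueError("f_x_meth must lie in [0, 1]")
        if self.f_x_meth > 0 and self.x_frac * self.n_promoter < 1:
            raise ValueError("f_x_meth > 0 requires X-linked methylation features")

    @property
    def xist_high_shift(self) -> float:
        """Log2 shift of the elevated XIST mode in male SLE; chosen so the
        mixture-mean interaction effect equals ``xist_interaction_lfc``."""
        return (self.xist_interaction_lfc + self.xist_female_sle_lfc) / self.pi_high

    @property
    def xist_mode_sd(self) -> float:
        return self.xist_high_shift / self.mode_separation_sd


@dataclass
class GroundTruth:
    true_lfc: dict  # modality -> DataFrame(features x contrasts)
    xist_class: pd.Series  # male SLE sample -> {high, low}
    xist_logexpr: pd.Series  # latent per-sample XIST log2 expression
    proportions: pd.DataFrame  # samples x cell types
    karyotype: pd.Series  # samples -> {XX, XY, XXY, XO}
    expected_cell_means: dict  # modality -> DataFrame(features x 5 cells)
    disease_activity: pd.Series


@dataclass
class CohortData:
    matrices: dict  # modality -> features x samples DataFrame
    samples: pd.DataFrame
    annotations: dict  # modality -> DataFrame(feature_id, chromosome)
    gene_lengths: pd.Series
    reference_profile: pd.DataFrame  # marker genes x cell types (TPM scale)
    flow: pd.DataFrame
    lod: pd.Series
    qc_flags: pd.DataFrame
    ground_truth: GroundTruth
    spec: CohortSpec

    def write(self, outdir) -> None:
        """Write matrices and metadata as the TSVs the pipeline reads;
        ground truth goes to a separate file never consumed by analysis."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for modality, mat in self.matrices.items():
            mat.to_csv(out / f"{modality}.tsv", sep="\t", index_label="feature_id")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
        for modality, ann in self.annotations.items():
            ann.to_csv(out / f"annotation_{modality}.tsv", sep="\t", index=False)
        self.flow.to_csv(out / "flow.tsv", sep="\t", index_label="sample_id")
        self.lod.rename("lod").to_csv(out / "lod.tsv", sep="\t", index_label="assay_id")
        truth = pd.DataFrame(
            {
                "karyotype": self.ground_truth.karyotype,
                "xist_logexpr": self.ground_truth.xist_logexpr,
            }
        )
        truth["xist_class"] = self.ground_truth.xist_class.reindex(truth.index)
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index_label="sample_id")


def _assign_chromosomes(rng, n: int, spec: CohortSpec) -> np.ndarray:
    autos = [str(c) for c in range(1, 23)]
    p_auto = (1 - spec.x_frac - spec.y_frac - spec.par_frac) / len(autos)
    labels = autos + ["X", "Y", "PAR"]
    probs = [p_auto] * len(autos) + [spec.x_frac, spec.y_frac, spec.par_frac]
    return rng.choice(labels, size=n, p=np.array(probs) / np.sum(probs))


def _logistic2(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + 2.0 ** (-z))


def simulate_cohort(spec: CohortSpec | None = None) -> CohortData:
    """Generate one cohort; deterministic given ``spec.seed``."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)

    # ---- samples -------------------------------------------------------
    groups = (
        [("F", "SLE")] * spec.n_f_sle
        + [("F", "HC")] * spec.n_f_hc
        + [("M", "SLE")] * spec.n_m_sle
        + [("M", "HC")] * spec.n_m_hc
    )
    sample_ids = [
        f"{sex}_{dis}_{i:04d}" for i, (sex, dis) in enumerate(groups)
    ]
    samples = pd.DataFrame(
        {"sex": [g[0] for g in groups], "disease": [g[1] for g in groups]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    sex = samples["sex"].to_numpy()
    disease = samples["disease"].to_numpy()
    is_f, is_m = sex == "F", sex == "M"
    is_sle = disease == "SLE"
    n_samples = len(samples)

    # karyotypes: euploid except the configured anomalies
    karyotype = pd.Series(np.where(is_m, "XY", "XX"), index=samples.index)
    m_ids = samples.index[is_m]
    f_ids = samples.index[is_f]
    if spec.n_xxy > 0:
        karyotype[rng.choice(m_ids, size=min(spec.n_xxy, len(m_ids)), replace=False)] = "XXY"
    if spec.n_xo > 0:
        karyotype[rng.choice(f_ids, size=min(spec.n_xo, len(f_ids)), replace=False)] = "XO"

    # latent XIST class for male SLE
    msle_mask = is_m & is_sle
    msle_ids = samples.index[msle_mask]
    xist_class = pd.Series(
        np.where(rng.random(len(msle_ids)) < spec.pi_high, "high", "low"),
        index=msle_ids,
    )

    # latent disease activity (higher in SLE; XIST-high males higher still)
    noise = 0.0 if spec.zero_noise else rng.normal(0, 1, n_samples)
    activity = pd.Series(np.where(is_sle, 1.5, 0.0) + noise, index=samples.index)
    activity[msle_ids] += np.where(xist_class == "high", 0.6, 0.0)

    # ---- cell-type proportions and flow --------------------------------
    alpha = np.array(spec.dirichlet_alpha)
    props = rng.dirichlet(alpha, size=n_samples)
    props = pd.DataFrame(props, index=samples.index, columns=CELL_TYPES)

    # ---- RNA-seq -------------------------------------------------------
    n_rna = spec.n_rna
    rna_chrom = _assign_chromosomes(rng, n_rna, spec)
    rna_chrom[0] = "X"  # the XIST-like transcript is always present
    rna_ids = np.array([f"g{i:05d}" for i in range(n_rna)])
    # name the signature genes: XIST on X, the interferon six on autosomes
    x_idx = np.flatnonzero(rna_chrom == "X")
    xist_i = x_idx[0]
    rna_ids[xist_i] = "XIST"
    auto_idx = np.flatnonzero(~np.isin(rna_chrom, ["X", "Y", "PAR"]))
    for j, name in enumerate(IFN_GENES):
        rna_ids[auto_idx[j]] = name
    ifn_idx = np.r_[auto_idx[: len(IFN_GENES)], auto_idx[len(IFN_GENES) : len(IFN_GENES) + spec.n_ifn_extra]]
    marker_idx = auto_idx[len(IFN_GENES) + spec.n_ifn_extra :][: spec.n_marker_genes]
    x_down_pool = x_idx[1:]
    n_x_down = int(round(spec.f_x_rna_down * len(x_down_pool)))
    x_down_idx = rng.choice(x_down_pool, size=n_x_down, replace=False) if n_x_down else np.array([], dtype=int)

    base_logcpm = rng.normal(5.0, 2.0, n_rna).clip(0.0, 12.0)
    base_logcpm[xist_i] = spec.xist_male_baseline_logcpm
    # rescale the composition so baseline CPMs sum to 1e6: planted log-CPM
    # values then translate into counts at the intended depth even though
    # only n_rna genes are simulated (the shift is uniform, so every
    # planted contrast is untouched)
    norm_shift = np.log2(1e6) - np.log2(np.sum(2.0**base_logcpm))
    base_logcpm = base_logcpm + norm_shift

    # reference profile for the mixture-driven marker genes (CPM scale,
    # on the same normalized composition as the baselines)
    marker_base = 2.0 ** (rng.normal(5.0, 1.5, len(marker_idx)) + norm_shift)
    ref = np.outer(marker_base, np.ones(len(CELL_TYPES)))
    per_type = np.array_split(np.arange(len(marker_idx)), len(CELL_TYPES))
    for c, rows in enumerate(per_type):
        ref[rows, c] *= 50.0
    reference_profile = pd.DataFrame(
        ref, index=rna_ids[marker_idx], columns=CELL_TYPES
    )

    # log2 expression per sample = baseline + planted effects
    logexpr = np.tile(base_logcpm[:, None], (1, n_samples))
    logexpr[np.ix_(ifn_idx, np.flatnonzero(is_sle))] += spec.ifn_lfc
    logexpr[np.ix_(x_down_idx, np.flatnonzero(msle_mask))] += spec.x_down_lfc

    # XIST: female baseline, female SLE shift, male SLE mixture (all on the
    # normalized composition scale)
    logexpr[xist_i, is_f] = spec.xist_female_baseline_logcpm + norm_shift
    logexpr[xist_i, is_f & is_sle] += spec.xist_female_sle_lfc
    # SLE inflates the variability (not the mean) of female XIST expression
    if not spec.zero_noise and spec.xist_female_sle_sd > 0:
        f_sle_pos = np.flatnonzero(is_f & is_sle)
        logexpr[xist_i, f_sle_pos] += rng.normal(
            0, spec.xist_female_sle_sd, len(f_sle_pos)
        )
    mode_noise = (
        np.zeros(len(msle_ids)) if spec.zero_noise else rng.normal(0, spec.xist_mode_sd, len(msle_ids))
    )
    msle_pos = np.flatnonzero(msle_mask)
    logexpr[xist_i, msle_pos] = (
        spec.xist_male_baseline_logcpm
        + norm_shift
        + np.where(xist_class.to_numpy() == "high", spec.xist_high_shift, 0.0)
        + mode_noise
    )
    xist_logexpr = pd.Series(logexpr[xist_i], index=samples.index)

    # neutrophil fraction co-varies negatively with XIST in females only
    if spec.neutro_xist_coupling > 0:
        fpos = np.flatnonzero(is_f)
        z = xist_logexpr.iloc[fpos]
        z = (z - z.mean()) / (z.std(ddof=0) or 1.0)
        scale = 2.0 ** (-spec.neutro_xist_coupling * z.to_numpy())
        neut = props.iloc[fpos]["Neutro"].to_numpy() * scale
        p = props.to_numpy()
        p[fpos, CELL_TYPES.index("Neutro")] = neut
        p[fpos] = p[fpos] / p[fpos].sum(axis=1, keepdims=True)
        props = pd.DataFrame(p, index=samples.index, columns=CELL_TYPES)

    flow_noise = 0.0 if spec.zero_noise else rng.normal(0, spec.flow_noise_sd, (n_samples, len(FLOW_GATES)))
    flow = (props[list(FLOW_GATES)] + flow_noise).clip(lower=0.0)

    # mixture-driven marker genes overwrite their baseline with Sum_c p_c R_gc
    logexpr[marker_idx, :] = np.log2(
        np.maximum(reference_profile.to_numpy() @ props.to_numpy().T, 1e-6)
    )

    # library sizes and counts
    if spec.zero_noise:
        lib = np.full(n_samples, spec.libsize_mean)
    else:
        sigma = np.sqrt(np.log(1 + spec.libsize_cv**2))
        lib = spec.libsize_mean * np.exp(rng.normal(-sigma**2 / 2, sigma, n_samples))
    mu = 2.0**logexpr * (lib / 1e6)[None, :]
    if spec.zero_noise or spec.nb_dispersion == 0:
        counts = mu
    else:
        size = 1.0 / spec.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu)).astype(float)
    rna = pd.DataFrame(counts, index=rna_ids, columns=samples.index)
    gene_lengths = pd.Series(
        (2.0 ** rng.uniform(10, 13.3, n_rna)).round(), index=rna_ids
    )

    # ---- methylation (promoter and gene level) -------------------------
    def make_meth(n_feat: int, prefix: str):
        chrom = _assign_chromosomes(rng, n_feat, spec)
        ids = np.array([f"{prefix}{i:05d}" for i in range(n_feat)])
        base = rng.normal(-1.0, 1.5, n_feat)
        z = np.tile(base[:, None], (1, n_samples))
        xi = np.flatnonzero(chrom == "X")
        n_aff = int(round(spec.f_x_meth * len(xi)))
        affected = rng.choice(xi, size=n_aff, replace=False) if n_aff else np.array([], dtype=int)
        z[np.ix_(affected, msle_pos)] += spec.delta_meth
        ai = np.flatnonzero(~np.isin(chrom, ["X", "Y", "PAR"]))
        hypo = ai[: spec.n_shared_hypo_meth]
        z[np.ix_(hypo, np.flatnonzero(is_sle))] += spec.shared_hypo_delta
        if not spec.zero_noise:
            z = z + rng.normal(0, spec.meth_logit_sd, z.shape)
        vals = _logistic2(z)
        return ids, chrom, base, affected, hypo, pd.DataFrame(vals, index=ids, columns=samples.index)

    p_ids, p_chrom, p_base, p_affected, p_hypo, promoter = make_meth(spec.n_promoter, "pr")
    g_ids, g_chrom, g_base, g_affected, g_hypo, gene_meth = make_meth(spec.n_gene_meth, "gm")

    # ---- protein NPX ---------------------------------------------------
    n_prot = spec.n_protein
    prot_ids = np.array([f"prot{i:05d}" for i in range(n_prot)])
    prot_chrom = np.array(
        ["X"] * spec.n_protein_x
        + list(
            rng.choice(
                [str(c) for c in range(1, 23)], size=n_prot - spec.n_protein_x
            )
        )
    )
    perm = rng.permutation(n_prot)
    prot_ids, prot_chrom = prot_ids, prot_chrom[perm]
    prot_base = rng.normal(3.0, 1.2, n_prot)
    prot_effect = np.zeros((n_prot, n_samples))
    pool = rng.permutation(n_prot)
    k = 0

    def take(n):
        nonlocal k
        out = pool[k : k + n]
        k += n
        return out

    shared_up = take(spec.n_protein_shared_up)
    shared_down = take(spec.n_protein_shared_down)
    female_only = take(spec.n_protein_female_only)
    male_only = take(spec.n_protein_male_only)
    f_sle = np.flatnonzero(is_f & is_sle)
    m_sle = msle_pos
    sle_pos = np.flatnonzero(is_sle)
    prot_effect[np.ix_(shared_up, sle_pos)] += spec.protein_effect
    prot_effect[np.ix_(shared_down, sle_pos)] -= spec.protein_effect
    f_signs = rng.choice([-1.0, 1.0], len(female_only))
    m_signs = rng.choice([-1.0, 1.0], len(male_only))
    prot_effect[np.ix_(female_only, f_sle)] += np.outer(
        f_signs * spec.protein_effect, np.ones(len(f_sle))
    )
    prot_effect[np.ix_(male_only, m_sle)] += np.outer(
        m_signs * spec.protein_effect, np.ones(len(m_sle))
    )
    npx_noise = 0.0 if spec.zero_noise else rng.normal(0, spec.npx_sd, (n_prot, n_samples))
    npx = pd.DataFrame(
        prot_base[:, None] + prot_effect + npx_noise,
        index=prot_ids,
        columns=samples.index,
    )
    lod = pd.Series(prot_base - spec.lod_margin, index=prot_ids)
    low_assays = rng.choice(
        n_prot, size=int(spec.frac_low_expressed * n_prot), replace=False
    )
    lod.iloc[low_assays] = prot_base[low_assays] + 1.0
    flags = pd.DataFrame("PASS", index=prot_ids, columns=samples.index)
    if spec.frac_fail_flags > 0 and not spec.zero_noise:
        fail = rng.random((n_prot, n_samples)) < spec.frac_fail_flags
        flags = flags.mask(fail, "FAIL")

    # ---- qPCR ----------------------------------------------------------
    ct_noise = 0.0 if spec.zero_noise else rng.normal(0, spec.ct_noise_sd, n_samples)
    ct_xist = spec.qpcr_intercept - spec.qpcr_slope * xist_logexpr.to_numpy() + ct_noise
    gapdh_noise = 0.0 if spec.zero_noise else rng.normal(0, spec.ct_noise_sd, n_samples)
    ct_gapdh = 20.0 + gapdh_noise
    samples["ct_xist"] = ct_xist
    samples["ct_gapdh"] = ct_gapdh
    if spec.n_missing_qpcr > 0:
        miss = rng.choice(msle_ids, size=min(spec.n_missing_qpcr, len(msle_ids)), replace=False)
        samples.loc[miss, "ct_xist"] = np.nan

    # ---- clinical variables -------------------------------------------
    def cnoise(sd):
        return 0.0 if spec.zero_noise else rng.normal(0, sd, n_samples)

    act = activity.to_numpy()
    xz = xist_logexpr.to_numpy()
    xz = (xz - xz.mean()) / xz.std(ddof=0)
    neut = props["Neutro"].to_numpy()
    tcell = props["T4"].to_numpy() + props["T8"].to_numpy()
    clin = {
        "sledai_2k": np.where(is_sle, 6 + 2 * act, 0.0) + cnoise(1.0),
        "igg_serum": 10 + 1.5 * np.where(is_m, xz, 0.0) + cnoise(2.0),
        "alk_phos": 70 + 8 * np.where(is_m, xz, 0.0) + cnoise(15.0),
        "neutrophil_count": 8 * neut + cnoise(0.3),
        "t_cell_count": 6 * tcell + cnoise(0.2),
        "bun": 14 - 1.2 * np.where(is_m, xz, 0.0) + cnoise(3.0),
        "eq5d_mobility": 2 - 0.3 * np.where(is_m, xz, 0.0) + cnoise(0.7),
        "disease_duration": np.clip(8 - 1.5 * np.where(is_m, xz, 0.0) + cnoise(4.0), 0, None),
    }
    for i in range(len(NAMED_NUMERIC), spec.n_numeric_clinical):
        clin[f"num_var_{i:02d}"] = rng.normal(0, 1, n_samples)
    apl_p = np.full(n_samples, 0.15)
    apl_p[msle_pos] = np.where(xist_class.to_numpy() == "high", 0.45, 0.15)
    clin["apl_status"] = np.where(rng.random(n_samples) < apl_p, "pos", "neg")
    for i in range(1, spec.n_categorical_clinical):
        clin[f"cat_var_{i:02d}"] = rng.choice(["a", "b"], n_samples)
    samples = pd.concat(
        [samples, pd.DataFrame(clin, index=samples.index)], axis=1
    )

    # ---- ground truth --------------------------------------------------
    cells = ["F_HC", "F_SLE", "M_HC", "M_SLE_low", "M_SLE_high"]

    def rna_cell_means():
        arr = np.tile(base_logcpm[:, None], (1, 5))
        arr[ifn_idx, 1] += spec.ifn_lfc  # F_SLE
        arr[ifn_idx, 3] += spec.ifn_lfc
        arr[ifn_idx, 4] += spec.ifn_lfc
        arr[x_down_idx, 3] += spec.x_down_lfc
        arr[x_down_idx, 4] += spec.x_down_lfc
        arr[xist_i, 0] = spec.xist_female_baseline_logcpm + norm_shift
        arr[xist_i, 1] = spec.xist_female_baseline_logcpm + norm_shift + spec.xist_female_sle_lfc
        arr[xist_i, 2] = spec.xist_male_baseline_logcpm + norm_shift
        arr[xist_i, 3] = spec.xist_male_baseline_logcpm + norm_shift
        arr[xist_i, 4] = spec.xist_male_baseline_logcpm + norm_shift + spec.xist_high_shift
        arr[marker_idx, :] = np.nan  # mixture-driven; no fixed cell mean
        return pd.DataFrame(arr, index=rna_ids, columns=cells)

    rna_means = rna_cell_means()
    mix_m_sle = spec.pi_high * rna_means["M_SLE_high"] + (1 - spec.pi_high) * rna_means["M_SLE_low"]
    rna_lfc = pd.DataFrame(
        {
            "female_SLE_vs_HC": rna_means["F_SLE"] - rna_means["F_HC"],
            "male_SLE_vs_HC": mix_m_sle - rna_means["M_HC"],
        }
    )
    rna_lfc["interaction"] = rna_lfc["male_SLE_vs_HC"] - rna_lfc["female_SLE_vs_HC"]
    rna_lfc = rna_lfc.fillna(0.0)

    def meth_truth(ids, base, affected, hypo):
        arr = np.tile(base[:, None], (1, 5))
        arr[hypo, 1] += spec.shared_hypo_delta
        arr[hypo, 3] += spec.shared_hypo_delta
        arr[hypo, 4] += spec.shared_hypo_delta
        arr[affected, 3] += spec.delta_meth
        arr[affected, 4] += spec.delta_meth
        means = pd.DataFrame(_logistic2(arr), index=ids, columns=cells)
        lfc = pd.DataFrame(
            {
                "female_SLE_vs_HC": arr[:, 1] - arr[:, 0],
                "male_SLE_vs_HC": arr[:, 3] - arr[:, 2],
            },
            index=ids,
        )
        lfc["interaction"] = lfc["male_SLE_vs_HC"] - lfc["female_SLE_vs_HC"]
        return means, lfc

    prom_means, prom_lfc = meth_truth(p_ids, p_base, p_affected, p_hypo)
    gm_means, gm_lfc = meth_truth(g_ids, g_base, g_affected, g_hypo)

    prot_lfc = pd.DataFrame(
        {
            "female_SLE_vs_HC": np.zeros(n_prot),
            "male_SLE_vs_HC": np.zeros(n_prot),
        },
        index=prot_ids,
    )
    prot_lfc.iloc[shared_up, :] = spec.protein_effect
    prot_lfc.iloc[shared_down, :] = -spec.protein_effect
    prot_lfc.iloc[female_only, 0] = f_signs * spec.protein_effect
    prot_lfc.iloc[male_only, 1] = m_signs * spec.protein_effect
    prot_lfc["interaction"] = prot_lfc["male_SLE_vs_HC"] - prot_lfc["female_SLE_vs_HC"]
    prot_means = pd.DataFrame(
        np.tile(prot_base[:, None], (1, 5)), index=prot_ids, columns=cells
    )
    prot_means["F_SLE"] += prot_lfc["female_SLE_vs_HC"].to_numpy()
    prot_means["M_SLE_low"] += prot_lfc["male_SLE_vs_HC"].to_numpy()
    prot_means["M_SLE_high"] += prot_lfc["male_SLE_vs_HC"].to_numpy()

    truth = GroundTruth(
        true_lfc={
            "rna": rna_lfc,
            "promoter_meth": prom_lfc,
            "gene_meth": gm_lfc,
            "protein_npx": prot_lfc,
        },
        xist_class=xist_class,
        xist_logexpr=xist_logexpr,
        proportions=props,
        karyotype=karyotype,
        expected_cell_means={
            "rna": rna_means,
            "promoter_meth": prom_means,
            "gene_meth": gm_means,
            "protein_npx": prot_means,
        },
        disease_activity=activity,
    )

    annotations = {
        "rna": pd.DataFrame({"feature_id": rna_ids, "chromosome": rna_chrom}),
        "promoter_meth": pd.DataFrame({"feature_id": p_ids, "chromosome": p_chrom}),
        "gene_meth": pd.DataFrame({"feature_id": g_ids, "chromosome": g_chrom}),
        "protein_npx": pd.DataFrame({"feature_id": prot_ids, "chromosome": prot_chrom}),
    }

    return CohortData(
        matrices={
            "rna_counts": rna,
            "promoter_meth": promoter,
            "gene_meth": gene_meth,
            "protein_npx": npx,
        },
        samples=samples,
        annotations=annotations,
        gene_lengths=gene_lengths,
        reference_profile=reference_profile,
        flow=flow,
        lod=lod,
        qc_flags=flags,
        ground_truth=truth,
        spec=spec,
    )


def simulate_read_depths(
    ground_truth: GroundTruth,
    base_coverage: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample per-chromosome mean coverage driven by karyotype.

    X coverage is proportional to X copy number relative to the two
    autosomal copies (XY and XO: 0.5x; XX and XXY: 1x); Y likewise.
    """
    rng = np.random.default_rng(seed)
    karyo = ground_truth.karyotype
    chroms = [str(c) for c in range(1, 23)] + ["X", "Y"]
    x_copies = karyo.map({"XX": 2, "XY": 1, "XXY": 2, "XO": 1}).to_numpy()
    y_copies = karyo.map({"XX": 0, "XY": 1, "XXY": 1, "XO": 0}).to_numpy()
    n = len(karyo)
    depth = np.full((n, len(chroms)), base_coverage)
    depth[:, chroms.index("X")] = base_coverage * x_copies / 2.0
    depth[:, chroms.index("Y")] = base_coverage * y_copies / 2.0
    if noise_sd > 0:
        depth = depth + rng.normal(0, noise_sd, depth.shape)
    return pd.DataFrame(depth, index=karyo.index, columns=chroms)
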