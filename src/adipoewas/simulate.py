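"""Synthetic two-wave multi-ethnic methylation study generator.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without restricted cohort data:

* four analysis strata (two Chinese sample sets plus Malay and Indian),
  each with baseline and follow-up visits ~6.8 (SD 1.39) years apart;
* array intensities (methylated/unmethylated signal, beadcounts) with typed
  control probes; negative controls set the background, the remaining
  control probes load on a latent per-sample batch score that also perturbs
  analytic probes;
* blood cell-type proportions drawn from a six-component Dirichlet, driving
  both designated reference probes (for deconvolution) and analytic probes;
* cis-mQTL SNP effects on a configurable fraction of probes, and trait SNPs
  whose dosages contribute to BMI (the backward-MR instrument);
* a cross-lagged BMI -> methylation structure: each causal probe carries a
  standardized residual process that responds to the previous wave's
  (non-demographic) BMI deviation, so the same probes produce cross-sectional
  EWAS signal and a forward CLPM path;
* IL-6 downstream of the true methylation risk score, TNF-alpha and most
  metabolites null;
* deliberately corrupted samples (high background, swapped sex) to exercise
  the QC filters.

Because methylation is generated downstream of BMI, the only well-defined
"true EWAS effect" for the trait-on-beta regression is the population partial
regression slope implied by the jointly linear model; it is recorded per
probe in the truth table (closed form in ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CELL_TYPES, CellReference
from .mr import Genotypes
from .qc import IntensityData

STRATA = ("MEC_Chinese", "iOmics_Chinese", "iOmics_Malay", "iOmics_Indian")
STRATUM_BMI_MEAN = {"MEC_Chinese": 23.5, "iOmics_Chinese": 23.5,
                    "iOmics_Malay": 26.5, "iOmics_Indian": 25.5}
SMOKING_PREV = {"MEC_Chinese": 0.0, "iOmics_Chinese": 0.25,
                "iOmics_Malay": 0.35, "iOmics_Indian": 0.30}
CELL_ALPHA = np.array([0.58, 0.08, 0.06, 0.15, 0.07, 0.06]) * 60.0
CONTROL_TYPES = ("BISULFITE_I", "BISULFITE_II", "EXTENSION", "HYBRIDIZATION",
                 "NORM_A", "NORM_C", "NORM_G", "NORM_T", "SPECIFICITY",
                 "STAINING", "TARGET_REMOVAL")


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_per_stratum: int = 100
    n_probes: int = 400
    n_snps: int = 60           # candidate cis SNPs (mQTL pool)
    n_trait_snps: int = 20     # SNPs with a true BMI effect (PRS pool)
    n_control_probes: int = 635
    n_negative_controls: int = 100
    n_cell_types: int = 6
    n_cell_ref_probes: int = 120
    n_sex_probes: int = 40     # half chrX, half chrY
    n_transcripts: int = 60
    n_metabolites: int = 155
    frac_causal_bmi_to_cpg: float = 0.10
    effect_scale_bmi_to_cpg: float = 0.002   # beta units per kg/m^2 (baseline BMI)
    frac_mqtl: float = 0.10
    mqtl_effect: float = 0.03                # beta units per allele
    allow_overlap: bool = True               # causal and mQTL sets may overlap
    ar_bmi: float = 0.6                      # a_x: BMI autoregression
    ar_cpg: float = 0.6                      # a_y: methylation autoregression
    cross_bmi_to_cpg: float = 0.3            # standardized c_xy for causal probes
    cross_cpg_to_bmi: float = 0.0            # standardized reverse path (composite)
    bmi_sd: float = 4.0                      # residual (non-demographic) BMI SD
    trait_snp_effect_sd: float = 0.35        # kg/m^2 per allele
    batch_sd: float = 0.010                  # beta-scale batch loading SD
    cell_sd: float = 0.050                   # beta-scale cell loading SD
    noise_sd: float = 0.020                  # beta-scale measurement noise SD
    mrs_to_il6: float = 0.30                 # standardized cross path MRS -> IL-6
    total_signal: float = 8000.0
    neg_control_mean: float = 60.0
    neg_control_sd: float = 15.0
    followup_years_mean: float = 6.8
    followup_years_sd: float = 1.39
    corrupt_missing_samples: tuple = ()      # sample ids or count, see resolve
    corrupt_sex_samples: tuple = ()
    n_lowbead_probes: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_causal_bmi_to_cpg", "frac_mqtl"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("batch_sd", "cell_sd", "noise_sd", "bmi_sd",
                     "followup_years_sd", "trait_snp_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_per_stratum", "n_probes", "n_snps", "n_control_probes",
                     "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if (not self.allow_overlap
                and self.frac_causal_bmi_to_cpg + self.frac_mqtl > 1):
            raise ValueError(
                "frac_causal_bmi_to_cpg + frac_mqtl > 1 requires allow_overlap=True")
        if self.n_negative_controls < 2 or self.n_negative_controls > self.n_control_probes:
            raise ValueError("need 2 <= n_negative_controls <= n_control_probes")


@dataclass
class StudyBundle:
    """Complete synthetic study with ground truth."""

    config: SynthConfig
    intensities: dict                  # visit -> IntensityData ("base", "fu")
    phenotypes: pd.DataFrame           # long: one row per sample x visit
    genotypes: Genotypes
    sumstats: pd.DataFrame
    expression: pd.DataFrame           # transcripts x samples (follow-up visit)
    transcript_coords: pd.DataFrame
    biomarkers: dict                   # visit -> samples x biomarker frame
    cell_reference: CellReference
    beta_true: dict                    # visit -> probe x sample observed beta
    truth: dict = field(default_factory=dict)

    def pheno(self, visit: str) -> pd.DataFrame:
        sub = self.phenotypes[self.phenotypes["visit"] == visit]
        return sub.set_index("sample_id")

    @property
    def samples(self) -> pd.Index:
        return self.intensities["fu"].samples


def _probe_manifest(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_probes
    ids = [f"cgS{i:06d}" for i in range(n)]
    chrom = [(i % 22) + 1 for i in range(n)]
    pos = [1_000_000 + (i // 22) * 2_000_000 for i in range(n)]
    relation = [("Island", "N_Shore", "S_Shore", "OpenSea")[i % 4] for i in range(n)]
    man = pd.DataFrame({
        "probe_id": ids, "chr": [str(c) for c in chrom], "pos": pos,
        "relation_to_island": relation,
        "gene": [f"GENE{i:04d}" for i in range(n)],
        "cross_reactive": rng.random(n) < 0.04,
        "snp_affected": rng.random(n) < 0.03,
    })
    # sex-check probes appended after the autosomal block
    sex_rows = []
    half = cfg.n_sex_probes // 2
    for i in range(cfg.n_sex_probes):
        is_x = i < half
        sex_rows.append({
            "probe_id": f"cg{'X' if is_x else 'Y'}{i:04d}",
            "chr": "X" if is_x else "Y",
            "pos": 1_000_000 + i * 100_000,
            "relation_to_island": "OpenSea",
            "gene": "", "cross_reactive": False, "snp_affected": False,
        })
    man = pd.concat([man, pd.DataFrame(sex_rows)], ignore_index=True)
    return man.set_index("probe_id")


def _resolve_corrupt(spec, samples: pd.Index, offset: int = 0) -> list[str]:
    """Corruption spec: an int count (deterministic slice) or explicit ids."""
    if isinstance(spec, int):
        return list(samples[offset:offset + spec])
    return [s for s in spec if s in samples]


def simulate_study(config: SynthConfig) -> StudyBundle:
    """Generate a full synthetic study; deterministic given ``config.seed``."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- samples & phenotypes -------------------------------------------
    sample_ids, strata = [], []
    for st in STRATA:
        for i in range(cfg.n_per_stratum):
            sample_ids.append(f"{st}_{i:04d}")
            strata.append(st)
    samples = pd.Index(sample_ids, name="sample_id")
    n = len(samples)
    stratum = pd.Series(strata, index=samples)

    age = np.clip(rng.normal(48, 10, n), 25, 75)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    smoking = np.array([rng.random() < SMOKING_PREV[s] for s in strata], dtype=int)
    followup = np.clip(rng.normal(cfg.followup_years_mean, cfg.followup_years_sd, n),
                       1.0, None)

    # genotypes: trait SNPs (BMI effects) + mQTL pool
    n_snps_total = cfg.n_snps + cfg.n_trait_snps
    snp_ids = [f"rsS{j:05d}" for j in range(n_snps_total)]
    maf = rng.uniform(0.1, 0.5, n_snps_total)
    dosages = rng.binomial(2, maf[:, None], size=(n_snps_total, n)).astype(float)
    trait_idx = np.arange(cfg.n_snps, n_snps_total)
    gamma = rng.normal(0, cfg.trait_snp_effect_sd, cfg.n_trait_snps)

    G = (gamma[None, :] * (dosages[trait_idx].T - 2 * maf[trait_idx])).sum(axis=1)
    var_g = float(np.sum(gamma**2 * 2 * maf[trait_idx] * (1 - maf[trait_idx])))
    sigma_e = np.sqrt(max(cfg.bmi_sd**2 - var_g, 0.25))
    sigma_v = np.sqrt(var_g + sigma_e**2)

    # non-demographic BMI deviation V, standardized driver z = V / sigma_v
    v0 = G + rng.normal(0, sigma_e, n)
    z0 = v0 / sigma_v
    a_x = cfg.ar_bmi

    # demographic BMI component (captured by EWAS covariates)
    b_age, b_sex = 0.05, 0.8
    demo0 = b_age * (age - 48) + b_sex * (sex == "M")
    demo1 = b_age * (age + followup - 48) + b_sex * (sex == "M")
    means = stratum.map(STRATUM_BMI_MEAN).to_numpy()

    # ---- probe architecture ---------------------------------------------
    manifest = _probe_manifest(cfg, rng)
    auto_probes = manifest.index[manifest["chr"].isin([str(c) for c in range(1, 23)])]
    p = len(auto_probes)

    n_causal = int(round(cfg.frac_causal_bmi_to_cpg * cfg.n_probes))
    n_mqtl = int(round(cfg.frac_mqtl * cfg.n_probes))
    order = rng.permutation(p)
    causal_idx = order[:n_causal]
    if cfg.allow_overlap:
        # mQTLs land on causal probes first, so association hits carry cis
        # instruments for the forward MR (as in the emulated study)
        mqtl_idx = order[:n_mqtl]
    else:
        mqtl_idx = order[n_causal:n_causal + n_mqtl]
    ref_idx = np.array(
        [i for i in order[::-1][:cfg.n_cell_ref_probes]
         if i not in set(causal_idx) and i not in set(mqtl_idx)], dtype=int)

    is_causal = np.zeros(p, bool); is_causal[causal_idx] = True
    is_mqtl = np.zeros(p, bool); is_mqtl[mqtl_idx] = True
    is_ref = np.zeros(p, bool); is_ref[ref_idx] = True

    a_y = cfg.ar_cpg
    c_xy = np.where(is_causal, cfg.cross_bmi_to_cpg, 0.0)
    rho0 = np.where(is_causal, cfg.cross_bmi_to_cpg, 0.0)  # baseline corr with z0
    # methylation scale per standardized residual unit, from the configured
    # beta-per-kg/m^2 effect: s = effect_scale * sigma_v / c_xy
    s_scale = np.full(p, 0.0)
    if cfg.cross_bmi_to_cpg > 0 and cfg.effect_scale_bmi_to_cpg > 0:
        s_scale[:] = cfg.effect_scale_bmi_to_cpg * sigma_v / cfg.cross_bmi_to_cpg
    else:
        s_scale[:] = 0.02  # inert residual scale for null worlds
    sign = rng.choice([-1.0, 1.0], p)
    c_xy = c_xy * sign
    rho0 = rho0 * sign

    # mQTL assignment: each mQTL probe gets one cis SNP from the pool
    mqtl_snp = np.array([None] * p, dtype=object)
    mqtl_eff = np.zeros(p)
    pool = list(rng.permutation(cfg.n_snps))
    snp_chr = np.empty(n_snps_total, dtype=object)
    snp_pos = np.zeros(n_snps_total, dtype=int)
    # default SNP coordinates: spread over chromosomes away from probes
    for j in range(n_snps_total):
        snp_chr[j] = str((j % 22) + 1)
        snp_pos[j] = 500_000 + (j // 22) * 2_000_000
    for i in mqtl_idx:
        if not pool:
            break
        j = pool.pop()
        mqtl_snp[i] = snp_ids[j]
        eff = cfg.mqtl_effect * rng.choice([-1.0, 1.0])
        mqtl_eff[i] = eff
        # place the SNP in cis: same chromosome, within 1 Mb
        row = manifest.loc[auto_probes[i]]
        snp_chr[j] = row["chr"]
        snp_pos[j] = int(row["pos"]) + int(rng.integers(-900_000, 900_000))

    # ---- latent processes ------------------------------------------------
    # residual process r per probe, cross-lagged on z (standardized BMI residual)
    r0 = rho0[:, None] * z0[None, :] + \
        np.sqrt(1 - rho0**2)[:, None] * rng.standard_normal((p, n))
    e_var = 1 - a_y**2 - c_xy**2 - 2 * a_y * c_xy * rho0
    e_var = np.clip(e_var, 0.05, None)
    r1 = a_y * r0 + c_xy[:, None] * z0[None, :] + \
        np.sqrt(e_var)[:, None] * rng.standard_normal((p, n))

    mrs0 = r0[is_causal].mean(axis=0) if is_causal.any() else np.zeros(n)
    if mrs0.std() > 0:
        mrs0 = (mrs0 - mrs0.mean()) / mrs0.std()
    z1 = a_x * z0 + cfg.cross_cpg_to_bmi * mrs0 + \
        np.sqrt(max(1 - a_x**2 - cfg.cross_cpg_to_bmi**2, 0.05)) * \
        rng.standard_normal(n)
    mrs1 = r1[is_causal].mean(axis=0) if is_causal.any() else np.zeros(n)
    if mrs1.std() > 0:
        mrs1 = (mrs1 - mrs1.mean()) / mrs1.std()

    bmi0 = means + demo0 + sigma_v * z0
    bmi1 = means + demo1 + sigma_v * z1
    wc_slope, wc_noise = 2.3, 4.0
    wc0 = 30 + wc_slope * bmi0 + rng.normal(0, wc_noise, n)
    wc1 = 30 + wc_slope * bmi1 + rng.normal(0, wc_noise, n)

    # cells and batch
    props = rng.dirichlet(CELL_ALPHA[:cfg.n_cell_types], size=n)  # n x types
    cell_load = rng.normal(0, cfg.cell_sd, (p, cfg.n_cell_types))
    batch_z = rng.standard_normal(n)
    batch_load = rng.normal(0, 1.0, p)

    # cell reference profiles for the deconvolution probes
    ref_probe_ids = auto_probes[is_ref]
    R = rng.uniform(0.05, 0.95, (len(ref_probe_ids), cfg.n_cell_types))
    cell_ref = CellReference(pd.DataFrame(
        R, index=ref_probe_ids, columns=list(CELL_TYPES[:cfg.n_cell_types])))

    # ---- observed methylation -------------------------------------------
    mu0_base = rng.uniform(0.15, 0.85, p)
    prop_centered = props - props.mean(axis=0)

    def _beta_wave(r_wave):
        base = (mu0_base[:, None]
                + cell_load @ prop_centered.T
                + cfg.batch_sd * batch_load[:, None] * batch_z[None, :]
                + s_scale[:, None] * r_wave)
        for i in np.where(is_mqtl)[0]:
            j = snp_ids.index(mqtl_snp[i])
            base[i] += mqtl_eff[i] * (dosages[j] - 2 * maf[j])
        base[is_ref] = (R @ props.T)
        noisy = base + rng.normal(0, cfg.noise_sd, (p, n))
        return np.clip(noisy, 0.001, 0.999)

    beta0 = _beta_wave(r0)
    beta1 = _beta_wave(r1)

    # ---- true EWAS slopes (population partial regression) ----------------
    var_extra = np.zeros(p)
    for i in np.where(is_mqtl)[0]:
        j = snp_ids.index(mqtl_snp[i])
        var_extra[i] = mqtl_eff[i]**2 * 2 * maf[j] * (1 - maf[j])
    num = s_scale * a_x * (a_y * rho0 + c_xy) * sigma_v
    den = s_scale**2 + cfg.noise_sd**2 + var_extra
    slope_bmi = num / den
    slope_bmi[is_ref] = 0.0
    # WC = 30 + wc_slope*BMI + noise: cov(beta, WC) scales by wc_slope while
    # var(beta | covariates) is unchanged, so the WC-on-beta slope scales too
    slope_wc = slope_bmi * wc_slope

    # ---- intensities -----------------------------------------------------
    all_probes = manifest.index
    n_all = len(all_probes)
    is_male = sex == "M"

    def _intensities(beta_obs, visit_rng):
        S = cfg.total_signal * np.exp(visit_rng.normal(0, 0.1, (n_all, n)))
        full_beta = np.vstack([
            beta_obs,
            visit_rng.uniform(0.2, 0.8, (cfg.n_sex_probes, n)),
        ])
        # sex probes: chrY at background for females, chrX halved for males
        half = cfg.n_sex_probes // 2
        x_rows = slice(p, p + half)
        y_rows = slice(p + half, p + cfg.n_sex_probes)
        # males: one X copy (halved), full Y; females: full X, Y at a low
        # cross-hybridization level still detectable above background
        S[x_rows, :] = np.where(is_male[None, :], S[x_rows, :] * 0.5, S[x_rows, :])
        S[y_rows, :] = np.where(is_male[None, :], S[y_rows, :],
                                cfg.total_signal / 16.0)
        M = full_beta * (S + 100.0)
        U = S - M
        U = np.clip(U, 0.0, None)
        bead = 3 + visit_rng.poisson(12, (n_all, n))
        return S, M, U, bead

    def _controls(visit_rng):
        ctrl_ids = [f"ctrl{k:04d}" for k in range(cfg.n_control_probes)]
        types = ["NEGATIVE"] * cfg.n_negative_controls + [
            CONTROL_TYPES[k % len(CONTROL_TYPES)]
            for k in range(cfg.n_control_probes - cfg.n_negative_controls)]
        sig = np.empty((cfg.n_control_probes, n))
        neg = slice(0, cfg.n_negative_controls)
        sig[neg] = visit_rng.normal(cfg.neg_control_mean, cfg.neg_control_sd,
                                    (cfg.n_negative_controls, n))
        n_rest = cfg.n_control_probes - cfg.n_negative_controls
        base_c = visit_rng.uniform(1000, 4000, n_rest)
        lam = visit_rng.normal(300, 60, n_rest)
        sig[cfg.n_negative_controls:] = (base_c[:, None]
                                         + lam[:, None] * batch_z[None, :]
                                         + visit_rng.normal(0, 30, (n_rest, n)))
        sig = np.clip(sig, 0.0, None)
        df = pd.DataFrame(sig, index=ctrl_ids, columns=samples)
        df.insert(0, "control_type", types)
        return df

    corrupt_miss = _resolve_corrupt(cfg.corrupt_missing_samples, samples)
    corrupt_sex = _resolve_corrupt(cfg.corrupt_sex_samples, samples,
                                   offset=len(corrupt_miss))

    lowbead_probes = list(auto_probes[~(is_causal | is_mqtl | is_ref)][:cfg.n_lowbead_probes])

    def _build_intensity(beta_obs, visit_seed):
        vrng = np.random.default_rng(visit_seed)
        S, M, U, bead = _intensities(beta_obs, vrng)
        ctrl = _controls(vrng)
        Mdf = pd.DataFrame(M, index=all_probes, columns=samples)
        Udf = pd.DataFrame(U, index=all_probes, columns=samples)
        Bdf = pd.DataFrame(bead, index=all_probes, columns=samples)
        for sid in corrupt_miss:
            # high background: 8% of probes collapse to background-level signal
            k = max(int(0.08 * n_all) + 1, 1)
            idx = all_probes[:k]
            Mdf.loc[idx, sid] = cfg.neg_control_mean * 0.4
            Udf.loc[idx, sid] = cfg.neg_control_mean * 0.4
        for probe in lowbead_probes:
            k = int(0.08 * n) + 1
            Bdf.loc[probe, Bdf.columns[:k]] = 1
        return IntensityData(M=Mdf, U=Udf, beadcount=Bdf, controls=ctrl,
                             manifest=manifest)

    sub_seed = int(rng.integers(0, 2**31 - 2))
    intens = {"base": _build_intensity(beta0, sub_seed),
              "fu": _build_intensity(beta1, sub_seed + 1)}

    # ---- phenotype sheet (long) ------------------------------------------
    reported_sex = pd.Series(sex, index=samples)
    for sid in corrupt_sex:
        reported_sex[sid] = "F" if reported_sex[sid] == "M" else "M"
    rows = []
    batch_assign = (np.arange(n) % 2) + 1
    for visit, bmi, wc, ages in (("base", bmi0, wc0, age),
                                 ("fu", bmi1, wc1, age + followup)):
        for i, sid in enumerate(samples):
            rows.append({
                "sample_id": sid, "visit": visit, "stratum": strata[i],
                "age": ages[i], "sex": reported_sex[sid],
                "smoking": smoking[i], "BMI": bmi[i], "WC": wc[i],
                "followup_time": followup[i], "batch": batch_assign[i],
            })
    phenotypes = pd.DataFrame(rows)

    genotypes = Genotypes(
        dosages=pd.DataFrame(dosages, index=snp_ids, columns=samples),
        coords=pd.DataFrame({
            "chr": snp_chr, "pos": snp_pos,
            "effect_allele": ["A"] * n_snps_total,
            "other_allele": ["G"] * n_snps_total,
            "maf": maf,
            "in_probe_binding": False,
        }, index=pd.Index(snp_ids, name="snp")),
    )

    truth_snps = pd.DataFrame({
        "snp": snp_ids, "maf": maf,
        "bmi_effect": [0.0] * cfg.n_snps + list(gamma),
        "is_trait_snp": [False] * cfg.n_snps + [True] * cfg.n_trait_snps,
    }).set_index("snp")
    sumstats = simulate_gwas_sumstats(truth_snps, genotypes.coords,
                                      n_external=170_000,
                                      seed=int(rng.integers(0, 2**31 - 1)))

    # ---- expression -------------------------------------------------------
    tr_ids = [f"TX{t:04d}" for t in range(cfg.n_transcripts)]
    causal_probe_ids = list(auto_probes[is_causal])
    tr_chr, tr_start, tr_target = [], [], []
    expr = np.abs(rng.normal(6, 1.0, (cfg.n_transcripts, n)))
    for t in range(cfg.n_transcripts):
        if causal_probe_ids and t < min(len(causal_probe_ids), cfg.n_transcripts // 2):
            pr = manifest.loc[causal_probe_ids[t]]
            tr_chr.append(pr["chr"])
            tr_start.append(int(pr["pos"]) + int(rng.integers(-800_000, 800_000)))
            tr_target.append(causal_probe_ids[t])
            i = list(auto_probes).index(causal_probe_ids[t])
            expr[t] += 8.0 * (beta1[i] - beta1[i].mean())
        else:
            tr_chr.append(str((t % 22) + 1))
            tr_start.append(200_000_000 + t * 10_000)
            tr_target.append(None)
    expression = pd.DataFrame(expr, index=tr_ids, columns=samples)
    transcript_coords = pd.DataFrame({
        "transcript_id": tr_ids, "chr": tr_chr, "start": tr_start,
        "cis_cpg": tr_target,
    })

    # ---- biomarkers -------------------------------------------------------
    def _biomarker_frames():
        il6_0 = 0.3 * mrs0 + rng.normal(0, np.sqrt(1 - 0.09), n)
        il6_1 = 0.5 * il6_0 + cfg.mrs_to_il6 * mrs0 + \
            rng.normal(0, np.sqrt(max(1 - 0.25 - cfg.mrs_to_il6**2, 0.05)), n)
        tnf_0 = rng.standard_normal(n)
        tnf_1 = 0.5 * tnf_0 + rng.normal(0, np.sqrt(0.75), n)
        frames = {}
        met_base = rng.standard_normal((cfg.n_metabolites, n))
        met_fu = 0.5 * met_base + rng.normal(0, np.sqrt(0.75),
                                             (cfg.n_metabolites, n))
        for k in range(min(4, cfg.n_metabolites)):
            met_fu[k] += cfg.mrs_to_il6 * mrs0
        for visit, il6, tnf, met in (("base", il6_0, tnf_0, met_base),
                                     ("fu", il6_1, tnf_1, met_fu)):
            cols = {"IL6": 3.0 + il6, "TNFa": 2.0 + tnf}
            cols.update({f"met{k:03d}": 10.0 + met[k]
                         for k in range(cfg.n_metabolites)})
            frames[visit] = pd.DataFrame(cols, index=samples)
        return frames

    biomarkers = _biomarker_frames()

    truth_probes = pd.DataFrame({
        "probe_id": auto_probes,
        "is_causal": is_causal, "is_mqtl": is_mqtl, "is_cell_ref": is_ref,
        "s_scale": s_scale, "c_xy": c_xy, "rho0": rho0,
        "mqtl_snp": mqtl_snp, "mqtl_effect": mqtl_eff,
        "ewas_slope_bmi": slope_bmi, "ewas_slope_wc": slope_wc,
    }).set_index("probe_id")
    truth_samples = pd.DataFrame(
        {"batch_z": batch_z, "true_sex": sex,
         "corrupt_missing": [s in set(corrupt_miss) for s in samples],
         "corrupt_sex": [s in set(corrupt_sex) for s in samples]},
        index=samples,
    )
    for t, name in enumerate(CELL_TYPES[:cfg.n_cell_types]):
        truth_samples[f"cell_{name}"] = props[:, t]

    truth = {
        "probes": truth_probes, "snps": truth_snps, "samples": truth_samples,
        "params": {"sigma_v": sigma_v, "var_g": var_g, "a_x": a_x, "a_y": a_y,
                   "wc_slope": wc_slope, "wc_noise": wc_noise,
                   "corrupt_missing": corrupt_miss, "corrupt_sex": corrupt_sex,
                   "lowbead_probes": lowbead_probes},
        "mrs": {"base": pd.Series(mrs0, index=samples),
                "fu": pd.Series(mrs1, index=samples)},
    }

    return StudyBundle(
        config=cfg, intensities=intens, phenotypes=phenotypes,
        genotypes=genotypes, sumstats=sumstats, expression=expression,
        transcript_coords=transcript_coords, biomarkers=biomarkers,
        cell_reference=cell_ref,
        beta_true={"base": pd.DataFrame(beta0, index=auto_probes, columns=samples),
                   "fu": pd.DataFrame(beta1, index=auto_probes, columns=samples)},
        truth=truth,
    )


def simulate_gwas_sumstats(
    truth_snps: pd.DataFrame,
    coords: pd.DataFrame,
    n_external: int,
    seed: int,
    pheno_sd: float = 4.5,
) -> pd.DataFrame:
    """External GWAS summary statistics as if estimated on n_external samples.

    Per SNP the sampling SE is ``pheno_sd / sqrt(n * 2 p (1-p))`` and the
    estimate is the true effect plus Normal noise of that SE; as
    ``n_external`` grows the estimates converge to the truth.

    ``truth_snps`` needs columns ``maf`` and ``bmi_effect`` indexed by SNP.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(seed)
    maf = truth_snps["maf"].to_numpy(dtype=float)
    true_eff = truth_snps["bmi_effect"].to_numpy(dtype=float)
    se = pheno_sd / np.sqrt(n_external * 2 * maf * (1 - maf))
    beta = true_eff + rng.normal(0, se)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * _stats.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "snp": truth_snps.index,
        "chr": coords.loc[truth_snps.index, "chr"].to_numpy(),
        "pos": coords.loc[truth_snps.index, "pos"].to_numpy(),
        "effect_allele": coords.loc[truth_snps.index, "effect_allele"].to_numpy(),
        "other_allele": coords.loc[truth_snps.index, "other_allele"].to_numpy(),
        "beta": beta, "se": se, "p": p, "n": n_external,
    })
    return out.reset_index(drop=True)
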