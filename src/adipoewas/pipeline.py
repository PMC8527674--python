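"""End-to-end orchestration of the adiposity EWAS analysis.

Stage order: simulate (optional) -> qc -> covars -> ewas -> meta -> clpm ->
mr -> scores (MRS + biomarker CLPM). Every stage writes its TSV outputs plus
a JSON provenance sidecar (input checksums, seed, package version); reruns
with the same configuration reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clpm as clpm_mod
from . import covariates as cov_mod
from . import ewas as ewas_mod
from . import io as io_mod
from . import meta as meta_mod
from . import mr as mr_mod
from .qc import QcThresholds, run_qc
from .simulate import SynthConfig, simulate_study

STAGES = ("simulate", "qc", "covars", "ewas", "meta", "clpm", "mr", "scores")


@dataclass
class RunConfig:
    """Pipeline settings; defaults echo the published analysis choices."""

    outdir: str = "run"
    seed: int = 0
    synth: dict = field(default_factory=dict)   # SynthConfig overrides
    qc: dict = field(default_factory=dict)      # QcThresholds overrides
    k_ctrl_pcs: int = 5
    cis_window_bp: int = 1_000_000
    novelty_window_bp: int = 500_000
    fdr_alpha: float = 0.05
    mr_alpha: float = 5e-4
    traits: tuple = ("BMI", "WC")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def validate_inputs(bundle) -> list[str]:
    """Schema and cross-component consistency checks; returns error strings."""
    errors = []
    pheno = bundle.phenotypes
    dup = pheno.duplicated(subset=["sample_id", "visit"])
    if dup.any():
        errors.append(f"duplicated sample_id/visit rows: "
                      f"{pheno.loc[dup, 'sample_id'].tolist()}")
    for col in ("BMI", "WC"):
        bad = pheno[pheno[col] <= 0]
        if len(bad):
            errors.append(f"{col} must be positive; offending samples "
                          f"{bad['sample_id'].tolist()[:5]}")
    if not set(pheno["smoking"].unique()) <= {0, 1}:
        errors.append("smoking must be coded 0/1")
    samples = set(bundle.samples)
    geno_samples = set(bundle.genotypes.dosages.columns)
    if not geno_samples <= samples:
        errors.append("genotype samples not present in intensity data: "
                      f"{sorted(geno_samples - samples)[:5]}")
    vals = bundle.genotypes.dosages.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        errors.append("genotype dosages outside [0, 2]")
    for visit, data in bundle.intensities.items():
        if (data.M.to_numpy() < 0).any() or (data.U.to_numpy() < 0).any():
            errors.append(f"negative intensities at visit {visit}")
        neg = data.controls["control_type"].eq("NEGATIVE").sum()
        if neg == 0:
            errors.append(f"no NEGATIVE control probes at visit {visit}")
    return errors


def validate_beta_frame(beta: pd.DataFrame) -> list[str]:
    """Schema check for a user-supplied beta matrix."""
    errors = []
    arr = beta.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    for i, j in bad[:10]:
        errors.append(f"beta value {arr[i, j]:g} outside [0,1] at probe "
                      f"{beta.index[i]}, sample {beta.columns[j]}")
    return errors


def _ewas_covariates(cells: pd.DataFrame, pcs: pd.DataFrame) -> pd.DataFrame:
    cells = cells.drop(columns=[c for c in ("sum",) if c in cells.columns])
    return cells.join(pcs)


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Execute the pipeline and return the run directory.

    ``stages`` restricts execution to a prefix of the stage order (each stage
    consumes in-memory results of the previous ones; earlier stages always
    run). Every stage writes TSV outputs plus a provenance sidecar; a failed
    stage leaves a ``FAILED`` marker naming the stage and error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = set(STAGES if stages is None else stages)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    last = max(STAGES.index(s) for s in wanted)
    todo = STAGES[: last + 1]

    state: dict = {}
    try:
        for stage in todo:
            _STAGE_FUNCS[stage](config, outdir, state)
            io_mod.write_provenance(
                outdir / f"{stage}.provenance.json",
                inputs={"config": json.dumps(dataclasses.asdict(config),
                                             sort_keys=True, default=str)},
                seed=config.seed, extra={"stage": stage})
    except Exception as exc:  # noqa: BLE001 - marker then re-raise
        (outdir / "FAILED").write_text(
            json.dumps({"stage": stage, "error": str(exc)}) + "\n")
        raise
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    return outdir


def _stage_simulate(config, outdir, state):
    synth = SynthConfig(**{"seed": config.seed, **config.synth})
    bundle = simulate_study(synth)
    errors = validate_inputs(bundle)
    if errors:
        raise ValueError("generated bundle failed validation: " + "; ".join(errors))
    state["bundle"] = bundle
    io_mod.write_bundle(bundle, outdir / "inputs")


def _stage_qc(config, outdir, state):
    bundle = state["bundle"]
    thresholds = QcThresholds(**config.qc)
    state["beta"], state["qc_reports"] = {}, {}
    for visit, data in bundle.intensities.items():
        sheet = bundle.pheno(visit).reset_index()
        beta, report = run_qc(data, sheet, thresholds)
        state["beta"][visit] = beta
        state["qc_reports"][visit] = report
        io_mod.write_tsv(report.sample_table.reset_index(names="sample_id"),
                         outdir / f"qc_samples_{visit}.tsv")
        io_mod.write_tsv(report.probe_table.reset_index(names="probe_id"),
                         outdir / f"qc_probes_{visit}.tsv")
        (outdir / f"qc_log_{visit}.txt").write_text(report.summary() + "\n")


def _stage_covars(config, outdir, state):
    bundle = state["bundle"]
    state["cells"], state["pcs"] = {}, {}
    for visit, beta in state["beta"].items():
        data = bundle.intensities[visit]
        ctrl = data.controls[beta.samples]
        pcs = cov_mod.control_probe_pcs(ctrl, k=config.k_ctrl_pcs)
        cells = cov_mod.houseman_deconvolve(beta, bundle.cell_reference)
        state["pcs"][visit] = pcs.scores
        state["cells"][visit] = cells
        io_mod.write_tsv(pcs.scores.reset_index(names="sample_id"),
                         outdir / f"control_pcs_{visit}.tsv")
        io_mod.write_tsv(cells.reset_index(names="sample_id"),
                         outdir / f"cell_proportions_{visit}.tsv")


def _stage_ewas(config, outdir, state):
    bundle = state["bundle"]
    beta = state["beta"]["fu"]
    covars = _ewas_covariates(state["cells"]["fu"], state["pcs"]["fu"])
    pheno = bundle.pheno("fu")
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for trait in config.traits:
            frames.append(ewas_mod.stratified_ewas(beta, pheno, covars, trait))
    state["ewas"] = pd.concat(frames, ignore_index=True)
    state["covars_fu"] = covars
    io_mod.write_tsv(state["ewas"], outdir / "ewas_stratum_estimates.tsv")


def _stage_meta(config, outdir, state):
    chinese, trans = meta_mod.hierarchical_meta(state["ewas"])
    state["meta_chinese"], state["meta"] = chinese, trans
    io_mod.write_tsv(chinese, outdir / "meta_chinese.tsv")
    io_mod.write_tsv(trans, outdir / "meta_trans_ethnic.tsv")
    hits = trans[trans["significant"]]
    state["hits"] = hits
    io_mod.write_tsv(hits, outdir / "significant_cpgs.tsv")


def _stage_clpm(config, outdir, state):
    bundle = state["bundle"]
    hits = state["hits"]
    bmi_hits = hits[hits["trait"] == "BMI"]["cpg"].unique()
    if len(bmi_hits) == 0:
        state["clpm"] = pd.DataFrame()
        io_mod.write_tsv(state["clpm"], outdir / "clpm_bmi.tsv")
        return
    pheno_b, pheno_f = bundle.pheno("base"), bundle.pheno("fu")
    beta_b, beta_f = state["beta"]["base"].beta, state["beta"]["fu"].beta
    keep = [c for c in bmi_hits if c in beta_b.index and c in beta_f.index]
    covars_meth_b = _ewas_covariates(state["cells"]["base"], state["pcs"]["base"])
    covars_meth_f = _ewas_covariates(state["cells"]["fu"], state["pcs"]["fu"])
    common = beta_b.columns.intersection(beta_f.columns)
    trait_cov_b = pheno_b.loc[common, ["age"]].assign(
        sex=(pheno_b.loc[common, "sex"] == "M").astype(float))
    trait_cov_f = pheno_f.loc[common, ["age"]].assign(
        sex=(pheno_f.loc[common, "sex"] == "M").astype(float))
    state["clpm"] = clpm_mod.clpm_scan(
        beta_b.loc[keep, common], beta_f.loc[keep, common],
        pheno_b.loc[common, "BMI"], pheno_f.loc[common, "BMI"],
        trait_cov_b, trait_cov_f,
        covars_meth_b.loc[common], covars_meth_f.loc[common])
    io_mod.write_tsv(state["clpm"], outdir / "clpm_bmi.tsv")


def _stage_mr(config, outdir, state):
    bundle = state["bundle"]
    hits = state["hits"]
    bmi_meta = state["meta"][state["meta"]["trait"] == "BMI"]
    hit_cpgs = hits[hits["trait"] == "BMI"]["cpg"].unique()
    beta = state["beta"]["fu"]
    manifest = beta.manifest
    hit_tab = pd.DataFrame({
        "cpg": hit_cpgs,
        "chr": manifest.loc[hit_cpgs, "chr"].to_numpy(),
        "pos": manifest.loc[hit_cpgs, "pos"].to_numpy(),
    })
    pheno = bundle.pheno("fu")
    covars = state["covars_fu"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iv = mr_mod.select_cis_iv(hit_tab, bundle.genotypes, beta, pheno, covars,
                                  window_bp=config.cis_window_bp)
        fwd, fwd_summary = mr_mod.forward_mr(iv, bundle.sumstats, bmi_meta,
                                             bundle.genotypes.coords,
                                             alpha=config.mr_alpha)
        # PRS SNPs: genome-wide significant trait associations in the
        # external summary statistics (the published-SNP analogue)
        weights = bundle.sumstats[bundle.sumstats["p"] < 5e-8]
        prs = mr_mod.compute_prs(bundle.genotypes, weights.rename(
            columns={"beta": "weight"})[["snp", "effect_allele", "weight"]])
        bwd, bwd_summary = mr_mod.backward_mr(
            prs, beta, pheno, covars, cpgs=list(hit_cpgs), alpha=config.mr_alpha)
    state["iv"], state["forward_mr"], state["backward_mr"] = iv, fwd, bwd
    state["mr_summaries"] = {"forward": fwd_summary, "backward": bwd_summary}
    io_mod.write_tsv(iv, outdir / "mr_instruments.tsv")
    io_mod.write_tsv(fwd, outdir / "mr_forward.tsv")
    io_mod.write_tsv(bwd, outdir / "mr_backward.tsv")
    (outdir / "mr_summary.json").write_text(
        json.dumps(state["mr_summaries"], indent=2, default=float) + "\n")


def _stage_scores(config, outdir, state):
    bundle = state["bundle"]
    bmi_meta = state["meta"][state["meta"]["trait"] == "BMI"]
    hits = bmi_meta[bmi_meta["significant"]]
    if len(hits) == 0:
        state["mrs_clpm"] = pd.DataFrame()
        return
    weights = hits.set_index("cpg")["effect"]
    mrs = {}
    for visit in ("base", "fu"):
        mrs[visit] = mr_mod.compute_mrs(state["beta"][visit], weights)
    pheno_b, pheno_f = bundle.pheno("base"), bundle.pheno("fu")
    common = mrs["base"].index.intersection(mrs["fu"].index)

    def _sexframe(ph):
        return pd.DataFrame({"age": ph.loc[common, "age"],
                             "sex": (ph.loc[common, "sex"] == "M").astype(float)},
                            index=common)

    covars_mrs_b = _sexframe(pheno_b).join(
        _ewas_covariates(state["cells"]["base"], state["pcs"]["base"]).loc[common])
    covars_mrs_f = _sexframe(pheno_f).join(
        _ewas_covariates(state["cells"]["fu"], state["pcs"]["fu"]).loc[common])
    covars_bio_b = _sexframe(pheno_b).assign(batch=pheno_b.loc[common, "batch"])
    covars_bio_f = _sexframe(pheno_f).assign(batch=pheno_f.loc[common, "batch"])
    state["mrs_clpm"] = clpm_mod.mrs_biomarker_clpm(
        mrs["base"][common], mrs["fu"][common],
        bundle.biomarkers["base"].loc[common], bundle.biomarkers["fu"].loc[common],
        covars_mrs_b, covars_mrs_f, covars_bio_b, covars_bio_f,
        followup_time=pheno_f.loc[common, "followup_time"])
    io_mod.write_tsv(state["mrs_clpm"], outdir / "mrs_biomarker_clpm.tsv")
    io_mod.write_tsv(mrs["fu"].rename("mrs").reset_index(),
                     outdir / "mrs_followup.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "covars": _stage_covars,
    "ewas": _stage_ewas,
    "meta": _stage_meta,
    "clpm": _stage_clpm,
    "mr": _stage_mr,
    "scores": _stage_scores,
}
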