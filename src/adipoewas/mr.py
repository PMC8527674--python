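"""Bidirectional Mendelian randomization and risk scores.

Forward MR asks whether methylation causes adiposity: for each
adiposity-associated CpG the top cis-mQTL SNP (smallest meta P within 1 Mb)
serves as instrument, its effect on the trait is taken from external GWAS
summary statistics, and the causal effect of CpG on trait is the Wald ratio
eff(trait~SNP) / eff(CpG~SNP) with a delta-method standard error. Backward MR
asks the reverse using a polygenic risk score (PRS) of trait-associated SNPs
as instrument: predicted trait -> CpG effect = eff(CpG~PRS) / eff(trait~PRS).
Predicted effects are compared with observed regression effects by a Pearson
correlation test. A methylation risk score (MRS) summarizes the hit CpGs as a
weighted sum of beta values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import ivw_meta
from .regression import design_matrix, ols_fit, slope_scan


@dataclass
class Genotypes:
    """Dosage matrix (SNP x sample, values in [0, 2]) with SNP coordinates.

    ``coords`` is indexed by SNP id with columns chr, pos, effect_allele,
    other_allele and optionally ``in_probe_binding`` (SNP lies within the
    probe-binding sequence of some CpG probe).
    """

    dosages: pd.DataFrame
    coords: pd.DataFrame

    def __post_init__(self):
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")


def wald_ratio(eff_outcome_iv: float, se_outcome_iv: float,
               eff_exposure_iv: float, se_exposure_iv: float) -> tuple[float, float]:
    """Wald-ratio causal estimate of exposure on outcome with delta-method SE.

    predicted = eff_outcome_iv / eff_exposure_iv (sign carried by the ratio);
    SE = sqrt( (eff_o^2/eff_e^2) * (se_o^2/eff_o^2 + se_e^2/eff_e^2) ),
    which reduces to |se_o / eff_e| in the eff_outcome_iv -> 0 limit.
    """
    if eff_exposure_iv == 0:
        raise ValueError("instrument-exposure effect must be nonzero")
    pred = eff_outcome_iv / eff_exposure_iv
    if eff_outcome_iv == 0:
        se = abs(se_outcome_iv / eff_exposure_iv)
    else:
        se = np.sqrt(
            (eff_outcome_iv**2 / eff_exposure_iv**2)
            * (se_outcome_iv**2 / eff_outcome_iv**2
               + se_exposure_iv**2 / eff_exposure_iv**2)
        )
    return float(pred), float(se)


def _meta_assoc_per_stratum(y_by_stratum, x_by_stratum, covar_by_stratum):
    """IVW meta of per-stratum slopes of y on x with covariates."""
    ests = []
    for y, x, C in zip(y_by_stratum, x_by_stratum, covar_by_stratum):
        eff, se, _, _ = slope_scan(y, x, C)
        if np.isfinite(se[0]) and se[0] > 0:
            ests.append((eff[0], se[0]))
    if not ests:
        return None
    return ivw_meta(ests)


def _stratum_blocks(pheno: pd.DataFrame, covars: pd.DataFrame, samples: pd.Index):
    """Per-stratum (samples, design) blocks for the discovery covariates."""
    from .ewas import _stratum_design

    blocks = []
    for stratum in sorted(pheno.loc[samples, "stratum"].unique()):
        s = samples.intersection(pheno.index[pheno["stratum"] == stratum])
        if len(s) < 5:
            continue
        blocks.append((s, _stratum_design(pheno, covars, s)))
    return blocks


def select_cis_iv(
    cpg_hits: pd.DataFrame,
    genotypes: Genotypes,
    beta,
    pheno: pd.DataFrame,
    covars: pd.DataFrame,
    trait: str = "BMI",
    window_bp: int = 1_000_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Select one cis-SNP instrument per CpG with the published exclusions.

    Per CpG, every non-monomorphic SNP within the closed 1 Mb window is
    regressed against the CpG beta with the discovery covariates per stratum
    and IVW-meta pooled; the smallest-P SNP is kept. Exclusion reasons:
    ``no_cis_snp``; ``nonsignificant`` (meta P > alpha); ``probe_binding``
    (SNP flagged inside the probe-binding sequence); ``pleiotropy_bmi``
    (SNP associated with the trait at P < alpha after adjusting for the CpG).
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    samples = bmat.columns.intersection(genotypes.dosages.columns).intersection(pheno.index)
    blocks = _stratum_blocks(pheno, covars, samples)
    coords = genotypes.coords
    rows = []
    for _, hit in cpg_hits.iterrows():
        cpg = hit["cpg"]
        cis = coords[
            (coords["chr"].astype(str) == str(hit["chr"]))
            & ((coords["pos"] - hit["pos"]).abs() <= window_bp)
        ].index
        cis = [s for s in cis
               if genotypes.dosages.loc[s, samples].std(ddof=1) > 0]
        if not cis:
            rows.append({"cpg": cpg, "snp": None, "eff_cpg_snp": np.nan,
                         "se_cpg_snp": np.nan, "p": np.nan,
                         "exclusion_reason": "no_cis_snp"})
            continue
        best = None
        for snp in cis:
            ests = []
            for s, C in blocks:
                y = bmat.loc[cpg, s].to_numpy(dtype=float)
                x = genotypes.dosages.loc[snp, s].to_numpy(dtype=float)
                eff, se, _, _ = slope_scan(y, x, C)
                if np.isfinite(se[0]) and se[0] > 0:
                    ests.append((eff[0], se[0]))
            if not ests:
                continue
            m = ivw_meta(ests)
            if best is None or m.p < best[1].p:
                best = (snp, m)
        if best is None:
            rows.append({"cpg": cpg, "snp": None, "eff_cpg_snp": np.nan,
                         "se_cpg_snp": np.nan, "p": np.nan,
                         "exclusion_reason": "no_cis_snp"})
            continue
        snp, m = best
        reason = "none"
        if m.p > alpha:
            reason = "nonsignificant"
        elif bool(coords.loc[snp].get("in_probe_binding", False)):
            reason = "probe_binding"
        else:
            # trait ~ SNP + CpG + covariates: pleiotropy check
            ests = []
            for s, C in blocks:
                y = pheno.loc[s, trait].to_numpy(dtype=float)
                X = np.column_stack([
                    genotypes.dosages.loc[snp, s].to_numpy(dtype=float),
                    bmat.loc[cpg, s].to_numpy(dtype=float),
                    C,
                ])
                try:
                    coef, se, _, _, _ = ols_fit(y, X)
                except np.linalg.LinAlgError:
                    continue
                ests.append((coef[0], se[0]))
            if ests and ivw_meta(ests).p < alpha:
                reason = "pleiotropy_bmi"
        rows.append({"cpg": cpg, "snp": snp, "eff_cpg_snp": m.effect,
                     "se_cpg_snp": m.se, "p": m.p, "exclusion_reason": reason})
    return pd.DataFrame(rows)


def harmonize_effect(snp: str, effect_allele: str, sumstats: pd.DataFrame):
    """Sumstats (beta, se) aligned to the stated effect allele.

    Flips the sign when the sumstats effect allele is the other allele;
    returns None when the SNP is absent or the alleles are irreconcilable.
    """
    sub = sumstats[sumstats["snp"] == snp]
    if len(sub) == 0:
        return None
    row = sub.iloc[0]
    if row["effect_allele"] == effect_allele:
        return float(row["beta"]), float(row["se"])
    if row.get("other_allele", None) == effect_allele:
        return -float(row["beta"]), float(row["se"])
    return None


def forward_mr(
    iv: pd.DataFrame,
    sumstats: pd.DataFrame,
    ewas_meta: pd.DataFrame,
    genotype_coords: pd.DataFrame,
    alpha: float = 5e-4,
) -> tuple[pd.DataFrame, dict]:
    """Forward MR: does methylation cause the trait?

    Surviving instruments (``exclusion_reason == 'none'``) are combined with
    external trait GWAS effects (allele-harmonized) via the Wald ratio. The
    predicted CpG -> trait effects are compared with the observed EWAS meta
    effects by a Pearson correlation test. A causal call requires the
    Wald-ratio Normal P below the Bonferroni-style ``alpha``.
    """
    obs = ewas_meta.set_index("cpg")["effect"]
    rows = []
    for _, r in iv.iterrows():
        if r["exclusion_reason"] != "none":
            continue
        ea = genotype_coords.loc[r["snp"], "effect_allele"]
        harm = harmonize_effect(r["snp"], ea, sumstats)
        if harm is None:
            rows.append({"cpg": r["cpg"], "snp": r["snp"],
                         "eff_trait_snp": np.nan, "se_trait_snp": np.nan,
                         "predicted_eff": np.nan, "predicted_se": np.nan,
                         "p": np.nan, "observed_eff": obs.get(r["cpg"], np.nan),
                         "causal": False, "reason": "no_sumstats"})
            continue
        b, s = harm
        pred, pse = wald_ratio(b, s, r["eff_cpg_snp"], r["se_cpg_snp"])
        p = 2.0 * stats.norm.sf(abs(pred / pse)) if pse > 0 else 0.0
        rows.append({"cpg": r["cpg"], "snp": r["snp"],
                     "eff_trait_snp": b, "se_trait_snp": s,
                     "predicted_eff": pred, "predicted_se": pse, "p": p,
                     "observed_eff": obs.get(r["cpg"], np.nan),
                     "causal": bool(p < alpha), "reason": ""})
    table = pd.DataFrame(rows)
    summary = _correlation_summary(table)
    return table, summary


def _correlation_summary(table: pd.DataFrame) -> dict:
    ok = table.dropna(subset=["predicted_eff", "observed_eff"]) if len(table) else table
    if len(ok) < 3:
        return {"n": len(ok), "r": np.nan, "p": np.nan,
                "n_causal": int(table["causal"].sum()) if len(table) else 0}
    r, p = stats.pearsonr(ok["predicted_eff"], ok["observed_eff"])
    return {"n": len(ok), "r": float(r), "p": float(p),
            "n_causal": int(table["causal"].sum())}


def compute_prs(genotypes: Genotypes, weights: pd.DataFrame) -> pd.Series:
    """Polygenic risk score: weighted allele-dosage sum per sample.

    ``weights`` needs columns snp, effect_allele, weight. Dosages are
    harmonized to each weight's effect allele (a flipped allele contributes
    ``w * (2 - dosage)``); missing dosages are mean-imputed per SNP.
    """
    score = pd.Series(0.0, index=genotypes.dosages.columns)
    n_used = 0
    for _, w in weights.iterrows():
        snp = w["snp"]
        if snp not in genotypes.dosages.index:
            continue
        d = genotypes.dosages.loc[snp].astype(float)
        if d.isna().any():
            d = d.fillna(d.mean())
        ea = genotypes.coords.loc[snp, "effect_allele"]
        oa = genotypes.coords.loc[snp].get("other_allele", None)
        if w["effect_allele"] == ea:
            score = score + w["weight"] * d
        elif oa is not None and w["effect_allele"] == oa:
            score = score + w["weight"] * (2.0 - d)
        else:
            continue
        n_used += 1
    if n_used == 0:
        raise ValueError("no weight SNPs overlap the genotype data")
    score.attrs["n_snps"] = n_used
    return score


def backward_mr(
    prs: pd.Series,
    beta,
    pheno: pd.DataFrame,
    covars: pd.DataFrame,
    cpgs=None,
    trait: str = "BMI",
    alpha: float = 5e-4,
) -> tuple[pd.DataFrame, dict]:
    """Backward MR: does the trait cause methylation change?

    The PRS instruments the trait. Per CpG the predicted trait -> CpG effect
    is eff(CpG~PRS) / eff(trait~PRS) with the delta-method SE; the observed
    effect is the regression of CpG beta on the trait with the discovery
    covariates (per stratum, IVW-meta pooled). A weak-instrument warning is
    attached when the PRS-trait association has P > 0.05.
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    if cpgs is None:
        cpgs = list(bmat.index)
    samples = bmat.columns.intersection(prs.index).intersection(pheno.index)
    blocks = _stratum_blocks(pheno, covars, samples)

    def _meta_slope(yfun, xfun):
        ests = []
        for s, C in blocks:
            eff, se, _, _ = slope_scan(yfun(s), xfun(s), C)
            if np.isfinite(se[0]) and se[0] > 0:
                ests.append((eff[0], se[0]))
        return ivw_meta(ests) if ests else None

    m_trait = _meta_slope(lambda s: pheno.loc[s, trait].to_numpy(dtype=float),
                          lambda s: prs[s].to_numpy(dtype=float))
    if m_trait is None or m_trait.effect == 0:
        raise ValueError("PRS-trait association could not be estimated")
    weak = m_trait.p > 0.05
    if weak:
        warnings.warn(f"weak instrument: PRS-{trait} association P = {m_trait.p:.3g}",
                      stacklevel=2)
    rows = []
    for cpg in cpgs:
        m_cpg = _meta_slope(lambda s: bmat.loc[cpg, s].to_numpy(dtype=float),
                            lambda s: prs[s].to_numpy(dtype=float))
        m_obs = _meta_slope(lambda s: bmat.loc[cpg, s].to_numpy(dtype=float),
                            lambda s: pheno.loc[s, trait].to_numpy(dtype=float))
        if m_cpg is None or m_obs is None:
            continue
        pred, pse = wald_ratio(m_cpg.effect, m_cpg.se, m_trait.effect, m_trait.se)
        p = 2.0 * stats.norm.sf(abs(pred / pse)) if pse > 0 else 0.0
        rows.append({"cpg": cpg, "predicted_eff": pred, "predicted_se": pse,
                     "p": p, "observed_eff": m_obs.effect,
                     "observed_se": m_obs.se, "causal": bool(p < alpha),
                     "weak_instrument": weak})
    table = pd.DataFrame(rows)
    summary = _correlation_summary(table)
    summary["prs_trait_effect"] = m_trait.effect
    summary["prs_trait_p"] = m_trait.p
    return table, summary


def compute_mrs(beta, weights: pd.Series, min_coverage: float = 0.5) -> pd.Series:
    """Methylation risk score: Z-standardized weighted sum of CpG betas.

    ``weights`` maps CpG id to weight (typically the trans-ethnic meta EWAS
    effects). Requires at least ``min_coverage`` of the weight CpGs present
    in the beta matrix and at least one nonzero weight.
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    present = weights.index.intersection(bmat.index)
    if len(present) < min_coverage * len(weights):
        raise ValueError(
            f"only {len(present)}/{len(weights)} weight CpGs present in beta matrix")
    w = weights[present]
    if (w == 0).all():
        raise ValueError("all MRS weights are zero")
    raw = bmat.loc[present].T @ w
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate MRS: zero variance")
    return (raw - raw.mean()) / sd
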