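"""Stratified epigenome-wide association of methylation with adiposity.

Per stratum and CpG, an ordinary least-squares model regresses the
untransformed trait (BMI in kg/m^2 or WC in cm) on the untransformed
methylation beta value, adjusting for age, sex, smoking (0 = never,
1 = ever), six blood cell-type fractions and the first five control-probe
PCs. The coefficient on beta is the reported effect (trait units per unit
beta), with t-based two-sided P-values. Also here: conditional analysis of
multi-CpG loci, cis expression association, expression pre-processing, and
below-detection-limit biomarker imputation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr, ivw_meta
from .qc import quantile_normalize
from .regression import design_matrix, ols_fit, slope_scan

EWAS_COVARIATES = "age + sex + smoking + 6 cell fractions + 5 control PCs"


def _stratum_design(pheno: pd.DataFrame, covars: pd.DataFrame, samples) -> np.ndarray:
    """Assemble the covariate design for one stratum's samples."""
    cols = {}
    ph = pheno.loc[samples]
    cols["age"] = ph["age"].to_numpy(dtype=float)
    sex = ph["sex"]
    cols["sex"] = (sex == "M").astype(float).to_numpy() if sex.dtype == object \
        else sex.to_numpy(dtype=float)
    if "smoking" in ph.columns:
        cols["smoking"] = ph["smoking"].to_numpy(dtype=float)
    cdf = pd.DataFrame(cols, index=samples)
    if covars is not None:
        cdf = cdf.join(covars.loc[samples])
    return design_matrix(cdf)[0]


def fit_ewas(
    beta,
    pheno: pd.DataFrame,
    covars: pd.DataFrame,
    trait: str,
    stratum: str | None = None,
) -> pd.DataFrame:
    """EWAS of one stratum: trait ~ beta + covariates, one model per CpG.

    Parameters
    ----------
    beta
        BetaMatrix or probe x sample DataFrame restricted to the stratum's
        samples (or a superset; the intersection with ``pheno`` rows is used).
    pheno
        Sample-indexed phenotype frame with ``age``, ``sex``, ``smoking`` and
        the trait column.
    covars
        Sample-indexed frame of additional covariates (cell fractions and
        control PCs).
    trait
        Phenotype column name (``BMI`` or ``WC``).

    Returns a StratumEstimate table: cpg, trait, stratum, n, beta_mean,
    beta_sd, effect, se, p, flag. Constant-beta CpGs are flagged ``constant``
    with NaN estimates.
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    samples = bmat.columns.intersection(pheno.index)
    if stratum is not None and "stratum" in pheno.columns:
        samples = samples.intersection(pheno.index[pheno["stratum"] == stratum])
    if len(samples) == 0:
        raise ValueError("no overlapping samples between beta matrix and phenotypes")
    C = _stratum_design(pheno, covars, samples)
    y = pheno.loc[samples, trait].to_numpy(dtype=float)
    X = bmat[samples].to_numpy(dtype=float).T  # samples x probes
    effect, se, p, df = slope_scan(y, X, C)
    out = pd.DataFrame(
        {
            "cpg": bmat.index,
            "trait": trait,
            "stratum": stratum if stratum is not None else "all",
            "n": len(samples),
            "beta_mean": X.mean(axis=0),
            "beta_sd": X.std(axis=0, ddof=1),
            "effect": effect,
            "se": se,
            "p": p,
        }
    )
    out["flag"] = np.where(np.isnan(effect), "constant", "")
    return out


def stratified_ewas(
    beta,
    pheno: pd.DataFrame,
    covars: pd.DataFrame,
    trait: str,
) -> pd.DataFrame:
    """Run fit_ewas separately in every stratum and stack the results."""
    frames = []
    for stratum in sorted(pheno["stratum"].unique()):
        frames.append(fit_ewas(beta, pheno, covars, trait, stratum=stratum))
    return pd.concat(frames, ignore_index=True)


def clump_loci(hits: pd.DataFrame, window_bp: int = 500_000) -> list[list[str]]:
    """Group significant CpGs into loci by single-linkage within a window.

    ``hits`` needs cpg, chr, pos. Returns the list of loci (each a list of
    CpG ids, position-sorted); loci of one CpG are included.
    """
    loci = []
    for _, sub in hits.sort_values(["chr", "pos"]).groupby("chr"):
        current: list[str] = []
        last = None
        for _, row in sub.iterrows():
            if last is not None and row["pos"] - last > window_bp:
                loci.append(current)
                current = []
            current.append(row["cpg"])
            last = row["pos"]
        if current:
            loci.append(current)
    return loci


def conditional_scan(
    beta,
    pheno: pd.DataFrame,
    covars: pd.DataFrame,
    trait: str,
    loci: list[list[str]],
    meta_results: pd.DataFrame | None = None,
    collinear_r: float = 0.99,
) -> pd.DataFrame:
    """Joint-CpG conditional analysis of multi-CpG loci.

    For each locus with >= 2 CpGs the sentinel (smallest meta P when
    ``meta_results`` is given, else first) is refit jointly with each other
    CpG per stratum; each conditional coefficient is meta-analyzed across
    strata. A secondary signal is declared when the non-sentinel CpG's
    conditional meta P falls below the Bonferroni bound 0.05 / n_loci.
    CpG pairs correlated above ``collinear_r`` are flagged, not called.
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    multi = [l for l in loci if len(l) >= 2]
    n_loci = len(multi)
    rows = []
    for locus in multi:
        if meta_results is not None:
            ps = meta_results.set_index("cpg")["p"].reindex(locus)
            sentinel = ps.idxmin()
        else:
            sentinel = locus[0]
        for other in locus:
            if other == sentinel:
                continue
            x1 = bmat.loc[sentinel]
            x2 = bmat.loc[other]
            r = float(np.corrcoef(x1, x2)[0, 1])
            if abs(r) > collinear_r:
                rows.append({"locus": "/".join(locus), "sentinel": sentinel,
                             "cpg": other, "r": r, "flag": "collinear",
                             "cond_effect": np.nan, "cond_se": np.nan,
                             "cond_p": np.nan, "secondary": False})
                continue
            ests = []
            for stratum in sorted(pheno["stratum"].unique()):
                samples = bmat.columns.intersection(
                    pheno.index[pheno["stratum"] == stratum])
                if len(samples) == 0:
                    continue
                C = _stratum_design(pheno, covars, samples)
                X = np.column_stack([
                    x1[samples].to_numpy(dtype=float),
                    x2[samples].to_numpy(dtype=float),
                    C,
                ])
                y = pheno.loc[samples, trait].to_numpy(dtype=float)
                coef, se, _, _, _ = ols_fit(y, X)
                ests.append((coef[1], se[1]))  # conditional coefficient of `other`
            m = ivw_meta(ests, cpg=other, trait=trait)
            rows.append({"locus": "/".join(locus), "sentinel": sentinel,
                         "cpg": other, "r": r, "flag": "",
                         "cond_effect": m.effect, "cond_se": m.se,
                         "cond_p": m.p,
                         "secondary": bool(n_loci and m.p < 0.05 / n_loci)})
    return pd.DataFrame(rows, columns=["locus", "sentinel", "cpg", "r", "flag",
                                       "cond_effect", "cond_se", "cond_p", "secondary"])


def cis_pairs(
    cpg_coords: pd.DataFrame,
    transcript_coords: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All (cpg, transcript) pairs with |pos - start| <= window on one chromosome.

    The window is a closed interval: a transcript exactly ``window_bp`` away
    is included. Coordinates are 1-based; the transcript start is used.
    """
    rows = []
    for _, c in cpg_coords.iterrows():
        t = transcript_coords[
            (transcript_coords["chr"].astype(str) == str(c["chr"]))
            & ((transcript_coords["start"] - c["pos"]).abs() <= window_bp)
        ]
        for _, tr in t.iterrows():
            rows.append({"cpg": c["cpg"], "transcript": tr["transcript_id"],
                         "distance": int(abs(tr["start"] - c["pos"]))})
    return pd.DataFrame(rows, columns=["cpg", "transcript", "distance"])


def cis_expression_assoc(
    cpg_hits: pd.DataFrame,
    expr: pd.DataFrame,
    transcript_coords: pd.DataFrame,
    beta,
    pheno: pd.DataFrame,
    covars: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Association of hit CpGs with transcripts within 1 Mb, IVW-meta pooled.

    Per stratum, expression (prepared by ``prepare_expression``) is regressed
    on CpG beta plus covariates; stratum estimates are pooled by fixed-effect
    meta-analysis and BH-FDR is applied across all tested pairs. CpGs with no
    cis transcript are recorded as untested (NaN row), not an error.
    """
    bmat = beta.beta if hasattr(beta, "beta") else beta
    pairs = cis_pairs(cpg_hits, transcript_coords, window_bp)
    rows = []
    tested_cpgs = set(pairs["cpg"]) if len(pairs) else set()
    for cpg in cpg_hits["cpg"]:
        if cpg not in tested_cpgs:
            rows.append({"cpg": cpg, "transcript": None, "distance": np.nan,
                         "effect": np.nan, "se": np.nan, "p": np.nan, "k": 0})
    strata = sorted(pheno["stratum"].unique())
    for _, pr in pairs.iterrows():
        if pr["transcript"] not in expr.index or pr["cpg"] not in bmat.index:
            continue
        ests = []
        for stratum in strata:
            samples = bmat.columns.intersection(expr.columns).intersection(
                pheno.index[pheno["stratum"] == stratum])
            if len(samples) < 5:
                continue
            C = _stratum_design(pheno, covars, samples)
            y = expr.loc[pr["transcript"], samples].to_numpy(dtype=float)
            x = bmat.loc[pr["cpg"], samples].to_numpy(dtype=float)
            eff, se, p, _ = slope_scan(y, x, C)
            if np.isfinite(se[0]):
                ests.append((eff[0], se[0]))
        if not ests:
            continue
        m = ivw_meta(ests, cpg=pr["cpg"])
        rows.append({"cpg": pr["cpg"], "transcript": pr["transcript"],
                     "distance": pr["distance"], "effect": m.effect,
                     "se": m.se, "p": m.p, "k": m.k})
    out = pd.DataFrame(rows)
    if len(out):
        tested = out["p"].notna()
        out["p_fdr"] = np.nan
        if tested.any():
            out.loc[tested, "p_fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def rank_inverse_normal(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (len(x) + 1 - 2 * offset))


def prepare_expression(
    expr_raw: pd.DataFrame,
    control_mean: float,
    covars: pd.DataFrame,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Expression pre-processing for the cis association analysis.

    Steps: (1) drop transcripts expressed below ``control_mean`` in strictly
    more than 90% of samples; (2) quantile-normalize samples; (3) residualize
    each transcript on the supplied covariates (sex, batch) plus the top
    ``n_pcs`` expression principal components, a surrogate for latent-factor
    (PEER-style) correction; (4) rank-inverse-normal transform the residuals
    (Blom offset 3/8).
    """
    low = (expr_raw < control_mean).mean(axis=1) > 0.90
    kept = expr_raw[~low]
    if len(kept) < 10:
        raise ValueError(f"fewer than 10 transcripts remain after low-expression filter "
                         f"({len(kept)})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qn = quantile_normalize(kept)
    X = qn.to_numpy(dtype=float).T
    Xc = X - X.mean(axis=0)
    n_pcs_eff = min(n_pcs, min(Xc.shape) - 1)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :n_pcs_eff] * s[:n_pcs_eff]
    cdf = covars.reindex(qn.columns).copy() if covars is not None \
        else pd.DataFrame(index=qn.columns)
    for i in range(n_pcs_eff):
        cdf[f"ePC{i + 1}"] = pcs[:, i]
    C, _ = design_matrix(cdf)
    coefs, *_ = np.linalg.lstsq(C, X, rcond=None)
    resid = X - C @ coefs
    out = np.apply_along_axis(rank_inverse_normal, 0, resid)
    return pd.DataFrame(out.T, index=qn.index, columns=qn.columns)


def prepare_biomarkers(table: pd.DataFrame, below_limit: pd.DataFrame) -> pd.DataFrame:
    """Impute below-detection-limit biomarker values.

    Entries flagged in the boolean ``below_limit`` mask are replaced by
    0.9 times the minimum observed above-limit value of that biomarker
    column; nothing else changes. A biomarker with every value below the
    limit becomes all-NaN with a warning.
    """
    out = table.copy().astype(float)
    mask = below_limit.reindex_like(table).fillna(False).astype(bool)
    for col in table.columns:
        m = mask[col]
        if not m.any():
            continue
        observed = table.loc[~m, col]
        if len(observed) == 0:
            warnings.warn(f"biomarker {col!r}: all values below detection limit; set to NaN",
                          stacklevel=2)
            out[col] = np.nan
            continue
        out.loc[m, col] = 0.9 * observed.min()
    return out
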