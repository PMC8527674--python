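"""Two-wave cross-lagged panel models (CLPM) for temporal inference.

Each variable is adjusted for its covariates by regression residuals and
Z-standardized per wave. The CLPM is the saturated two-wave path model:

    follow-up X ~ a_x * baseline X + c_yx * baseline Y + e2
    follow-up Y ~ a_y * baseline Y + c_xy * baseline X + e1

with the baseline correlation rho estimated as the Pearson r. For this
saturated model the maximum-likelihood path estimates coincide with the OLS
multiple-regression coefficients (the equivalence is asserted against a
numerical SEM likelihood fit in the tests), and the comparative fit index
(CFI), evaluated against the independence baseline model, is 1 by
construction; it is reported for completeness. The cross paths c_xy
(baseline X -> follow-up Y) and c_yx index temporal precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr
from .regression import design_matrix, ols_fit


@dataclass
class ClpmFit:
    """Standardized two-wave path estimates for one (X, Y) pair."""

    rho_baseline: float
    a_x: float
    a_y: float
    c_xy: float          # baseline X -> follow-up Y
    c_yx: float          # baseline Y -> follow-up X
    se_a_x: float
    se_a_y: float
    se_c_xy: float
    se_c_yx: float
    p_a_x: float
    p_a_y: float
    p_c_xy: float
    p_c_yx: float
    resid_corr: float
    cfi: float
    n: int


def residualize_standardize(values, covars=None) -> np.ndarray:
    """OLS residuals on the covariates, then Z-standardized (ddof=1).

    With no covariates (intercept only) this is a plain z-score. Raises on
    zero residual variance (constant input or perfect covariate fit).
    """
    y = np.asarray(values, dtype=float).ravel()
    if covars is None:
        covars = pd.DataFrame(index=range(len(y)))
    C, _ = design_matrix(covars)
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    resid = y - C @ coef
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-12:
        raise ValueError("zero residual variance; cannot standardize")
    return (resid - resid.mean()) / sd


def _check_standardized(v: np.ndarray, name: str) -> None:
    if abs(v.mean()) > 1e-6 or abs(v.std(ddof=1) - 1.0) > 1e-6:
        raise ValueError(f"{name} is not standardized (mean {v.mean():.2g}, "
                         f"sd {v.std(ddof=1):.4g})")


def fit_clpm(x_base, x_fu, y_base, y_fu, ml_se: bool = False) -> ClpmFit:
    """Fit the saturated two-wave cross-lagged panel model.

    All four inputs must be residualized/standardized vectors over the same
    samples (checked to 1e-6). ``ml_se=True`` rescales the OLS path SEs by
    sqrt(df/n), the maximum-likelihood convention.
    """
    arrs = [np.asarray(v, dtype=float).ravel() for v in (x_base, x_fu, y_base, y_fu)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all four vectors must cover the same samples")
    if n < 10:
        raise ValueError(f"need n >= 10 samples, got {n}")
    for a, name in zip(arrs, ("x_base", "x_fu", "y_base", "y_fu")):
        _check_standardized(a, name)
    xb, xf, yb, yf = arrs

    design = np.column_stack([np.ones(n), xb, yb])
    coef_x, se_x, p_x, df, resid_x = ols_fit(xf, design)
    coef_y, se_y, p_y, _, resid_y = ols_fit(yf, design)
    if ml_se:
        scale = np.sqrt(df / n)
        se_x = se_x * scale
        se_y = se_y * scale
        p_x = 2.0 * stats.norm.sf(np.abs(coef_x / se_x))
        p_y = 2.0 * stats.norm.sf(np.abs(coef_y / se_y))

    rho = float(np.corrcoef(xb, yb)[0, 1])
    resid_corr = float(np.corrcoef(resid_x, resid_y)[0, 1])

    # CFI vs the independence baseline on the 4-variable correlation matrix;
    # the saturated model has zero discrepancy, so CFI = 1 unless the
    # baseline itself fits (then 1 by the max-0 convention too).
    R = np.corrcoef(np.column_stack([xb, yb, xf, yf]).T)
    sign, logdet = np.linalg.slogdet(R)
    t_baseline = -(n - 1) * logdet if sign > 0 else np.inf
    df_baseline = 6
    num = max(0.0, 0.0 - 0.0)  # saturated model: T_M - df_M = 0
    den = max(num, t_baseline - df_baseline, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den

    return ClpmFit(
        rho_baseline=rho,
        a_x=float(coef_x[1]), a_y=float(coef_y[2]),
        c_xy=float(coef_y[1]), c_yx=float(coef_x[2]),
        se_a_x=float(se_x[1]), se_a_y=float(se_y[2]),
        se_c_xy=float(se_y[1]), se_c_yx=float(se_x[2]),
        p_a_x=float(p_x[1]), p_a_y=float(p_y[2]),
        p_c_xy=float(p_y[1]), p_c_yx=float(p_x[2]),
        resid_corr=resid_corr, cfi=float(cfi), n=n,
    )


def _fit_row(label: str, fit: ClpmFit) -> dict:
    return {
        "pair": label, "n": fit.n, "rho_base": fit.rho_baseline,
        "a_x": fit.a_x, "a_y": fit.a_y,
        "c_xy": fit.c_xy, "se_c_xy": fit.se_c_xy, "p_c_xy": fit.p_c_xy,
        "c_yx": fit.c_yx, "se_c_yx": fit.se_c_yx, "p_c_yx": fit.p_c_yx,
        "resid_corr": fit.resid_corr, "cfi": fit.cfi,
    }


def clpm_scan(
    beta_base: pd.DataFrame,
    beta_fu: pd.DataFrame,
    trait_base: pd.Series,
    trait_fu: pd.Series,
    covars_trait_base: pd.DataFrame,
    covars_trait_fu: pd.DataFrame,
    covars_meth_base: pd.DataFrame,
    covars_meth_fu: pd.DataFrame,
) -> pd.DataFrame:
    """CLPM of trait vs each CpG over samples measured at both waves.

    X is the trait (adjusted for its covariates per wave), Y each CpG
    (adjusted for its covariates per wave); ``c_xy`` is therefore the
    trait -> methylation path. CpGs missing at a wave are skipped. The
    returned table carries BH-FDR adjusted P for both cross paths.
    """
    samples = (beta_base.columns.intersection(beta_fu.columns)
               .intersection(trait_base.index).intersection(trait_fu.index))
    if len(samples) < 10:
        raise ValueError("fewer than 10 two-wave samples")
    xb = residualize_standardize(trait_base[samples], covars_trait_base.loc[samples])
    xf = residualize_standardize(trait_fu[samples], covars_trait_fu.loc[samples])
    cmb = covars_meth_base.loc[samples]
    cmf = covars_meth_fu.loc[samples]
    rows = []
    shared = beta_base.index.intersection(beta_fu.index)
    for cpg in shared:
        try:
            yb = residualize_standardize(beta_base.loc[cpg, samples], cmb)
            yf = residualize_standardize(beta_fu.loc[cpg, samples], cmf)
        except ValueError:
            continue
        fit = fit_clpm(xb, xf, yb, yf)
        rows.append({"cpg": cpg, **_fit_row(cpg, fit)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr_c_xy"] = bh_fdr(out["p_c_xy"].to_numpy())
        out["p_fdr_c_yx"] = bh_fdr(out["p_c_yx"].to_numpy())
    return out


def mrs_biomarker_clpm(
    mrs_base: pd.Series,
    mrs_fu: pd.Series,
    biomarkers_base: pd.DataFrame,
    biomarkers_fu: pd.DataFrame,
    covars_mrs_base: pd.DataFrame,
    covars_mrs_fu: pd.DataFrame,
    covars_bio_base: pd.DataFrame,
    covars_bio_fu: pd.DataFrame,
    followup_time: pd.Series | None = None,
) -> pd.DataFrame:
    """CLPM of the methylation risk score against each biomarker.

    Biomarkers are residualized on their covariates (age, sex, batch), the
    MRS on its covariates (age, sex, cell fractions, control PCs); when
    ``followup_time`` is given it is added to both follow-up-wave
    residualizations. X is the MRS, so ``c_xy`` is the MRS -> biomarker
    path. All-NaN biomarkers are skipped.
    """
    samples = (mrs_base.index.intersection(mrs_fu.index)
               .intersection(biomarkers_base.index).intersection(biomarkers_fu.index))
    if len(samples) < 10:
        raise ValueError("fewer than 10 two-wave samples")
    cmf = covars_mrs_fu.loc[samples].copy()
    cbf = covars_bio_fu.loc[samples].copy()
    if followup_time is not None:
        cmf["followup_time"] = followup_time.reindex(samples)
        cbf["followup_time"] = followup_time.reindex(samples)
    xb = residualize_standardize(mrs_base[samples], covars_mrs_base.loc[samples])
    xf = residualize_standardize(mrs_fu[samples], cmf)
    rows = []
    for col in biomarkers_base.columns.intersection(biomarkers_fu.columns):
        b0 = biomarkers_base.loc[samples, col]
        b1 = biomarkers_fu.loc[samples, col]
        if b0.isna().all() or b1.isna().all():
            continue
        ok = b0.notna() & b1.notna()
        if ok.sum() < 10 or not ok.all():
            # complete-case restriction would break the shared-sample design;
            # analyze the complete subset instead
            sub = samples[ok]
            try:
                yb = residualize_standardize(b0[sub], covars_bio_base.loc[sub])
                yf = residualize_standardize(b1[sub], cbf.loc[sub])
                xbs = residualize_standardize(mrs_base[sub], covars_mrs_base.loc[sub])
                xfs = residualize_standardize(mrs_fu[sub], cmf.loc[sub])
                fit = fit_clpm(xbs, xfs, yb, yf)
            except ValueError:
                continue
        else:
            try:
                yb = residualize_standardize(b0, covars_bio_base.loc[samples])
                yf = residualize_standardize(b1, cbf)
            except ValueError:
                continue
            fit = fit_clpm(xb, xf, yb, yf)
        rows.append({"biomarker": col, **_fit_row(col, fit)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr_c_xy"] = bh_fdr(out["p_c_xy"].to_numpy())
        out["p_fdr_c_yx"] = bh_fdr(out["p_c_yx"].to_numpy())
    return out
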