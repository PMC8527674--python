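"""Fixed-effect meta-analysis, FDR, replication lookups and novelty annotation.

Stratified EWAS estimates are pooled with inverse-variance-weighted (IVW)
fixed-effect meta-analysis: weights ``w_i = 1/SE_i^2``, pooled effect
``sum(w_i e_i)/sum(w_i)``, pooled ``SE = sum(w_i)^{-1/2}``, and Cochran's Q
heterogeneity statistic on ``k - 1`` degrees of freedom. The pooling scheme is
hierarchical: the two Chinese sample sets are meta-analyzed first, then the
combined Chinese evidence is pooled with the Malay and Indian strata. For a
fixed-effect model the two-stage pooled effect and SE are algebraically
identical to pooling the four base strata directly; heterogeneity is reported
over the four base strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CHINESE_STRATA = ("MEC_Chinese", "iOmics_Chinese")
NON_CHINESE_STRATA = ("iOmics_Malay", "iOmics_Indian")


@dataclass
class MetaResult:
    """Pooled fixed-effect estimate for one CpG/trait."""

    cpg: str
    trait: str
    effect: float
    se: float
    p: float
    q_stat: float
    df: int
    p_het: float
    k: int
    stratum_effects: np.ndarray = field(default_factory=lambda: np.array([]))
    stratum_ses: np.ndarray = field(default_factory=lambda: np.array([]))
    p_fdr: float = np.nan


def ivw_meta(estimates, cpg: str = "", trait: str = "") -> MetaResult:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    Parameters
    ----------
    estimates
        Sequence of ``(effect, se)`` pairs, one per stratum. All SEs must be
        strictly positive.

    Returns
    -------
    MetaResult
        Pooled effect, SE, two-sided Normal P, Cochran's Q with ``k - 1``
        degrees of freedom and its upper-tail chi-square P.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("ivw_meta requires at least one stratum estimate")
    est = est.reshape(-1, 2)
    effects, ses = est[:, 0], est[:, 1]
    if np.any(ses <= 0) or np.any(~np.isfinite(ses)):
        raise ValueError("all standard errors must be finite and > 0")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * effects) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (effects - pooled) ** 2))
    k = len(effects)
    df = k - 1
    p_het = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return MetaResult(
        cpg=cpg, trait=trait, effect=pooled, se=se, p=p,
        q_stat=q, df=df, p_het=p_het, k=k,
        stratum_effects=effects, stratum_ses=ses,
    )


def hierarchical_meta(stratum_results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage (Chinese-first) meta-analysis over stratified EWAS results.

    Parameters
    ----------
    stratum_results
        Long table with columns ``cpg, trait, stratum, effect, se`` (extra
        columns pass through untouched). Strata named ``MEC_Chinese``,
        ``iOmics_Chinese``, ``iOmics_Malay``, ``iOmics_Indian``; missing
        strata are pooled over with a warning.

    Returns
    -------
    (chinese_meta, trans_ethnic_meta)
        Stage-1 pools the Chinese sample sets; stage-2 pools all four base
        strata (effect/SE identical to pooling Chinese-meta with the Malay and
        Indian strata; heterogeneity computed over the base strata). Both
        tables carry BH-FDR adjusted P.
    """
    import warnings

    required = {"cpg", "trait", "stratum", "effect", "se"}
    missing = required - set(stratum_results.columns)
    if missing:
        raise ValueError(f"stratum_results missing columns: {sorted(missing)}")

    known = set(CHINESE_STRATA) | set(NON_CHINESE_STRATA)
    seen = set(stratum_results["stratum"].unique())
    if not seen <= known:
        raise ValueError(f"unrecognised strata: {sorted(seen - known)}")
    if seen != known:
        warnings.warn(
            f"strata missing from input, pooling over available: {sorted(known - seen)}",
            stacklevel=2,
        )

    clean = stratum_results.dropna(subset=["effect", "se"])
    if (clean["se"] <= 0).any():
        raise ValueError("all standard errors must be > 0")

    def _pool(sub: pd.DataFrame) -> pd.DataFrame:
        # vectorized IVW pooling over (cpg, trait) groups
        w = 1.0 / sub["se"] ** 2
        g = sub.assign(w=w, we=w * sub["effect"]).groupby(
            ["cpg", "trait"], sort=True)
        agg = g.agg(k=("w", "size"), sw=("w", "sum"), swe=("we", "sum"))
        agg["effect"] = agg["swe"] / agg["sw"]
        agg["se"] = agg["sw"] ** -0.5
        agg["p"] = 2.0 * stats.norm.sf(np.abs(agg["effect"] / agg["se"]))
        pooled = agg["effect"].reindex(
            pd.MultiIndex.from_frame(sub[["cpg", "trait"]])).to_numpy()
        q = (w * (sub["effect"].to_numpy() - pooled) ** 2) \
            .groupby([sub["cpg"].to_numpy(), sub["trait"].to_numpy()]).sum()
        agg["q_stat"] = q.to_numpy()
        agg["df"] = agg["k"] - 1
        agg["p_het"] = np.where(agg["df"] > 0,
                                stats.chi2.sf(agg["q_stat"], agg["df"]), 1.0)
        out = agg.reset_index()[["cpg", "trait", "k", "effect", "se", "p",
                                 "q_stat", "df", "p_het"]]
        if len(out):
            out["p_fdr"] = bh_fdr(out["p"].to_numpy())
            out["significant"] = out["p_fdr"] < 0.05
        else:
            out["p_fdr"] = []
            out["significant"] = []
        return out

    chinese = _pool(clean[clean["stratum"].isin(CHINESE_STRATA)])
    trans = _pool(clean)
    return chinese, trans


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_consistency(hits: pd.DataFrame, external: pd.DataFrame) -> dict:
    """Cross-study sign concordance with an exact binomial test.

    Both tables need columns ``cpg`` and ``effect``. CpGs present in both
    tables are compared by sign of effect; CpGs with an effect of exactly zero
    in either table are excluded from both counts. The two-sided exact
    binomial test is against a null concordance proportion of 0.5.

    Returns a dict with ``n_overlap``, ``n_concordant``, ``proportion``,
    ``binom_p`` (NaN when there is no overlap).
    """
    merged = hits[["cpg", "effect"]].merge(
        external[["cpg", "effect"]], on="cpg", suffixes=("_hit", "_ext")
    )
    merged = merged[(merged["effect_hit"] != 0) & (merged["effect_ext"] != 0)]
    n = len(merged)
    if n == 0:
        return {"n_overlap": 0, "n_concordant": 0, "proportion": np.nan, "binom_p": np.nan}
    conc = int((np.sign(merged["effect_hit"]) == np.sign(merged["effect_ext"])).sum())
    p = stats.binomtest(conc, n, 0.5, alternative="two-sided").pvalue
    return {
        "n_overlap": n,
        "n_concordant": conc,
        "proportion": conc / n,
        "binom_p": float(p),
    }


def annotate_novelty(
    hits: pd.DataFrame,
    catalog: pd.DataFrame,
    window_bp: int = 500_000,
    obesity_genes=None,
) -> pd.DataFrame:
    """Flag hits as novel relative to a catalog of known trait associations.

    A hit is novel iff no catalog entry for the same trait lies strictly
    within ``window_bp`` on the same chromosome — i.e. novelty requires a
    distance strictly greater than the window, so a known association at
    exactly ``window_bp`` renders the hit NOT novel.

    ``hits`` needs ``cpg, chr, pos, trait``; ``catalog`` needs
    ``chr, pos, trait`` (malformed rows are skipped and counted in the
    ``n_catalog_skipped`` attribute of the result). When ``obesity_genes`` is
    given and hits carry a ``gene`` column, an ``obesity_gene`` flag is added.
    """
    out = hits.copy()
    cat = catalog.copy()
    n_skip = 0
    for col in ("chr", "pos", "trait"):
        if col not in cat.columns:
            raise ValueError(f"catalog missing column {col!r}")
    cat["pos"] = pd.to_numeric(cat["pos"], errors="coerce")
    bad = cat["pos"].isna() | cat["chr"].isna() | cat["trait"].isna()
    n_skip = int(bad.sum())
    cat = cat[~bad]

    novel = []
    for _, row in out.iterrows():
        same = cat[
            (cat["trait"] == row["trait"])
            & (cat["chr"].astype(str) == str(row["chr"]))
        ]
        if len(same) == 0:
            novel.append(True)
        else:
            dist = (same["pos"] - float(row["pos"])).abs()
            novel.append(bool((dist > window_bp).all()))
    out["novel"] = novel
    if obesity_genes is not None and "gene" in out.columns:
        geneset = set(obesity_genes)
        out["obesity_gene"] = out["gene"].isin(geneset)
    out.attrs["n_catalog_skipped"] = n_skip
    return out


def load_novel_cpg_table() -> pd.DataFrame:
    """Published per-stratum estimates for the six novel adiposity CpGs.

    Long table (cpg, trait, stratum, beta_mean, beta_sd, effect, se, p) of the
    reported association statistics in the four analysis strata; input surface
    for reproducing the pooled meta-analysis results.
    """
    with resources.files("adipoewas.data").joinpath(
        "novel_cpg_stratum_estimates.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
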