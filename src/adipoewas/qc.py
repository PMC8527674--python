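"""Intensity-level QC and normalization for methylation array data.

Pipeline order: background correction (negative-control based) -> detection
P-values -> sample filters (missingness, sex check) -> probe filters
(detection, beadcount, sex chromosomes) -> within-group quantile
normalization -> beta values ``M / (M + U + 100)``.

Default thresholds: detection P > 1e-16 failing in > 5% of probes excludes a
sample; a probe is excluded when it fails detection in > 5% of samples or has
beadcount < 3 in > 5% of samples; sex-chromosome probes are always excluded;
cross-reactive and SNP-affected probes are flagged but retained. The sex
check compares log2 median total intensity of chrY vs chrX probes: a
difference > -2 indicates male.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass
class QcThresholds:
    """Filter thresholds; defaults follow the published protocol."""

    detp_alpha: float = 1e-16      # detection P above this counts as a failure
    sample_miss_frac: float = 0.05  # sample dropped if failing frac strictly exceeds
    beadcount_min: int = 3
    probe_fail_frac: float = 0.05   # probe dropped if failing frac strictly exceeds
    sexcheck_cut: float = -2.0      # log2(medY) - log2(medX) above this => male

    def header(self) -> str:
        return (
            f"detP>{self.detp_alpha:g} in >{self.sample_miss_frac:.0%} (sample), "
            f"detP in >{self.probe_fail_frac:.0%} samples / beadcount<{self.beadcount_min} "
            f"in >{self.probe_fail_frac:.0%} samples (probe), sexcheck cut {self.sexcheck_cut:g}"
        )


@dataclass
class IntensityData:
    """Raw or corrected probe-level intensities.

    ``M``, ``U`` and ``beadcount`` are probe x sample DataFrames sharing index
    and columns; ``controls`` holds one row per control probe with a
    ``control_type`` column (at least one NEGATIVE) followed by per-sample
    signal columns; ``manifest`` is indexed by probe_id with at least
    ``chr`` and ``pos`` plus optional ``cross_reactive``/``snp_affected``
    flags.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    beadcount: pd.DataFrame
    controls: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self):
        if not (self.M.shape == self.U.shape == self.beadcount.shape):
            raise ValueError("M, U and beadcount must share dimensions")
        if not (self.M.index.equals(self.U.index) and self.M.columns.equals(self.U.columns)):
            raise ValueError("M and U must share index and columns")

    @property
    def samples(self) -> pd.Index:
        return self.M.columns

    @property
    def probes(self) -> pd.Index:
        return self.M.index

    def total(self) -> pd.DataFrame:
        return self.M + self.U

    def negative_controls(self) -> pd.DataFrame:
        neg = self.controls[self.controls["control_type"] == "NEGATIVE"]
        if len(neg) == 0:
            raise ValueError("no NEGATIVE control probes present")
        return neg[self.samples]


@dataclass
class BetaMatrix:
    """Normalized methylation fractions in [0, 1) with probe annotations."""

    beta: pd.DataFrame
    manifest: pd.DataFrame
    normalization: str = "none"

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns


@dataclass
class QcReport:
    """Per-sample and per-probe exclusion bookkeeping."""

    sample_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    probe_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    thresholds: QcThresholds = field(default_factory=QcThresholds)

    @property
    def excluded_samples(self) -> pd.DataFrame:
        return self.sample_table[self.sample_table["excluded"]]

    @property
    def excluded_probes(self) -> pd.DataFrame:
        return self.probe_table[self.probe_table["excluded"]]

    def summary(self) -> str:
        lines = [f"QC thresholds: {self.thresholds.header()}"]
        if len(self.sample_table):
            counts = self.excluded_samples["reason"].value_counts()
            lines.append(f"samples: {len(self.sample_table)} in, "
                         f"{len(self.excluded_samples)} excluded "
                         f"({dict(counts)})")
        if len(self.probe_table):
            counts = self.excluded_probes["reason"].value_counts()
            lines.append(f"probes: {len(self.probe_table)} in, "
                         f"{len(self.excluded_probes)} excluded ({dict(counts)})")
        return "\n".join(lines)


def background_correct(data: IntensityData) -> IntensityData:
    """Subtract per-sample background estimated from negative controls.

    The background ``b`` for each sample is the 5th percentile (linear
    interpolation) of its negative-control signals; ``M`` and ``U`` are
    shifted by ``-b`` and floored at zero.
    """
    neg = data.negative_controls()
    b = neg.quantile(0.05, axis=0)  # per sample
    M = (data.M - b).clip(lower=0.0)
    U = (data.U - b).clip(lower=0.0)
    return replace(data, M=M, U=U)


def detection_pvalues(data: IntensityData) -> pd.DataFrame:
    """Detection P-value per probe and sample.

    Upper-tail Normal probability of the total signal M + U under the
    per-sample background distribution Normal(mean, sd) of negative-control
    signals; small P means confidently above background.
    """
    neg = data.negative_controls()
    if len(neg) < 2:
        raise ValueError("need >= 2 negative controls per sample for detection P")
    mu = neg.mean(axis=0)
    sd = neg.std(axis=0, ddof=1)
    total = data.total()
    if (sd == 0).any():
        warnings.warn("zero negative-control SD in some samples; detection P is a 0/1 step",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (total - mu) / sd
        detp = pd.DataFrame(stats.norm.sf(z), index=total.index, columns=total.columns)
        # sd == 0: degenerate step function at the mean
        zero_sd = sd == 0
        if zero_sd.any():
            cols = sd.index[zero_sd]
            step = (total[cols] <= mu[cols]).astype(float)
            detp[cols] = step
    return detp


def infer_sex(data: IntensityData) -> pd.DataFrame:
    """Sex check from sex-chromosome probe intensities.

    Returns a per-sample frame with ``sexcheck_diff`` (log2 median total
    intensity of chrY minus chrX probes) and ``inferred_sex`` ('M' when the
    difference exceeds the -2 cut, else 'F'). Empty when the manifest has no
    probes on either sex chromosome (caller warns and skips).
    """
    chrom = data.manifest.loc[data.probes, "chr"].astype(str)
    x_probes = data.probes[chrom.isin({"X", "chrX"})]
    y_probes = data.probes[chrom.isin({"Y", "chrY"})]
    if len(x_probes) == 0 or len(y_probes) == 0:
        return pd.DataFrame(columns=["sexcheck_diff", "inferred_sex"])
    total = data.total()
    diff = np.log2(total.loc[y_probes].median(axis=0)) - np.log2(
        total.loc[x_probes].median(axis=0)
    )
    out = pd.DataFrame({"sexcheck_diff": diff})
    out["inferred_sex"] = np.where(diff > -2.0, "M", "F")
    return out


def filter_samples(
    data: IntensityData,
    detp: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[IntensityData, QcReport]:
    """Exclude samples by probe missingness and sex mismatch.

    A sample is excluded when strictly more than ``sample_miss_frac`` of its
    probes have detection P above ``detp_alpha`` (reason ``missingness``), or
    when the sex inferred from chrX/chrY intensities disagrees with the
    self-reported ``sex`` column of ``sample_sheet`` (reason ``sex_mismatch``).
    Each excluded sample carries exactly one primary reason; missingness takes
    precedence.
    """
    thr = thresholds or QcThresholds()
    fail_frac = (detp > thr.detp_alpha).mean(axis=0)
    table = pd.DataFrame({"miss_frac": fail_frac})
    table["excluded"] = False
    table["reason"] = ""
    miss = fail_frac > thr.sample_miss_frac
    table.loc[miss, ["excluded", "reason"]] = [True, "missingness"]

    sexinfo = infer_sex(data)
    if len(sexinfo) == 0:
        warnings.warn("no chrX/chrY probes in manifest; sex check skipped", stacklevel=2)
        table["sexcheck_diff"] = np.nan
        table["inferred_sex"] = ""
    else:
        table = table.join(sexinfo)
        if sample_sheet is not None and "sex" in sample_sheet.columns:
            reported = sample_sheet.set_index("sample_id")["sex"] \
                if "sample_id" in sample_sheet.columns else sample_sheet["sex"]
            reported = reported.reindex(table.index)
            mismatch = (table["inferred_sex"] != reported) & reported.notna() & ~table["excluded"]
            table.loc[mismatch, ["excluded", "reason"]] = [True, "sex_mismatch"]

    keep = table.index[~table["excluded"]]
    filtered = replace(
        data,
        M=data.M[keep], U=data.U[keep], beadcount=data.beadcount[keep],
        controls=pd.concat(
            [data.controls.drop(columns=list(data.samples)), data.controls[keep]], axis=1
        ),
    )
    report = QcReport(sample_table=table, thresholds=thr)
    return filtered, report


def filter_probes(
    data: IntensityData,
    detp: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[IntensityData, QcReport]:
    """Exclude probes by detection, beadcount and sex-chromosome rules.

    Exclusion reasons (first applicable wins): ``detection`` when detection P
    exceeds the threshold in strictly more than ``probe_fail_frac`` of
    samples; ``beadcount`` when beadcount < ``beadcount_min`` in strictly
    more than the same fraction; ``sex_chromosome`` for chrX/chrY probes.
    Cross-reactive and SNP-affected probes are flagged, never dropped.
    """
    thr = thresholds or QcThresholds()
    detp = detp[data.samples]
    det_frac = (detp.loc[data.probes] > thr.detp_alpha).mean(axis=1)
    bead_frac = (data.beadcount < thr.beadcount_min).mean(axis=1)
    chrom = data.manifest.loc[data.probes, "chr"].astype(str)

    table = pd.DataFrame(
        {"detp_fail_frac": det_frac, "beadcount_fail_frac": bead_frac, "chr": chrom}
    )
    table["excluded"] = False
    table["reason"] = ""

    det_bad = det_frac > thr.probe_fail_frac
    bead_bad = bead_frac > thr.probe_fail_frac
    sex_bad = chrom.isin(SEX_CHROMS)
    table.loc[det_bad, ["excluded", "reason"]] = [True, "detection"]
    newly = bead_bad & ~table["excluded"]
    table.loc[newly, ["excluded", "reason"]] = [True, "beadcount"]
    newly = sex_bad & ~table["excluded"]
    table.loc[newly, ["excluded", "reason"]] = [True, "sex_chromosome"]

    for flag in ("cross_reactive", "snp_affected"):
        if flag in data.manifest.columns:
            table[flag] = data.manifest.loc[data.probes, flag].astype(bool)
        else:
            table[flag] = False

    keep = table.index[~table["excluded"]]
    if len(keep) == 0:
        raise ValueError("no probes remain after probe filtering")
    filtered = replace(
        data,
        M=data.M.loc[keep], U=data.U.loc[keep], beadcount=data.beadcount.loc[keep],
        manifest=data.manifest.loc[keep],
    )
    report = QcReport(probe_table=table, thresholds=thr)
    return filtered, report


def quantile_normalize(matrix: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Quantile normalization of sample columns within groups.

    Within each group every sample's sorted value vector is replaced by the
    cross-sample mean of sorted vectors; ties within a sample receive the
    average of the tied reference values (average-rank rule), preserving rank
    order. Groups of size 1 are returned unchanged with a warning.
    """
    if groups is None:
        groups = pd.Series("all", index=matrix.columns)
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    out = matrix.copy().astype(float)
    for g, cols in groups.groupby(groups).groups.items():
        cols = list(cols)
        if len(cols) == 1:
            warnings.warn(f"group {g!r} has a single sample; left unchanged", stacklevel=2)
            continue
        sub = matrix[cols].to_numpy(dtype=float)
        ref = np.sort(sub, axis=0).mean(axis=1)
        n = sub.shape[0]
        normed = np.empty_like(sub)
        for j in range(sub.shape[1]):
            col = sub[:, j]
            order = np.argsort(col, kind="mergesort")
            sorted_vals = col[order]
            if not (sorted_vals[1:] == sorted_vals[:-1]).any():
                ranks = np.empty(n, dtype=float)
                ranks[order] = ref
            else:
                # average-of-tied-ranks: each value maps to the mean of the
                # reference over its tie block
                ranks = np.empty(n, dtype=float)
                i = 0
                while i < n:
                    k = i
                    while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                        k += 1
                    ranks[order[i:k + 1]] = ref[i:k + 1].mean()
                    i = k + 1
            normed[:, j] = ranks
        out[cols] = normed
    return out


def compute_beta(data: IntensityData, normalization: str = "none") -> BetaMatrix:
    """Beta values ``M / (M + U + 100)``; always in [0, 1)."""
    if (data.M.to_numpy() < 0).any() or (data.U.to_numpy() < 0).any():
        raise ValueError("negative signal intensities")
    beta = data.M / (data.M + data.U + 100.0)
    return BetaMatrix(beta=beta, manifest=data.manifest.loc[data.probes],
                      normalization=normalization)


def run_qc(
    data: IntensityData,
    sample_sheet: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    norm_groups: pd.Series | None = None,
) -> tuple[BetaMatrix, QcReport]:
    """End-to-end QC: background-correct -> detP -> sample filters ->
    probe filters -> per-group quantile normalization (beta scale) -> beta.

    ``norm_groups`` defaults to the ``stratum`` column of the sample sheet
    when present (normalization within each sample-set/ethnicity group),
    else a single group.
    """
    thr = thresholds or QcThresholds()
    corrected = background_correct(data)
    detp = detection_pvalues(corrected)
    by_sample, sample_report = filter_samples(corrected, detp, sample_sheet, thr)
    by_probe, probe_report = filter_probes(by_sample, detp[by_sample.samples], thr)

    if norm_groups is None and "stratum" in sample_sheet.columns:
        sheet = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet.columns \
            else sample_sheet
        norm_groups = sheet["stratum"].reindex(by_probe.samples)

    raw_beta = compute_beta(by_probe)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta = quantile_normalize(raw_beta.beta, norm_groups)
    report = QcReport(
        sample_table=sample_report.sample_table,
        probe_table=probe_report.probe_table,
        thresholds=thr,
    )
    return BetaMatrix(beta=beta, manifest=by_probe.manifest,
                      normalization="quantile(by stratum)"), report
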