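# Methods and design notes

## The analysis

The package implements a stratified epigenome-wide association analysis of
adiposity with follow-up causal inference. Per stratum (sample set ×
ethnicity) and CpG, the model is

    trait_i = β0 + β1·methylation_i + age + sex + smoking
              + 6 cell fractions + 5 control-probe PCs + ε_i

with the untransformed trait (BMI in kg/m², WC in cm) as outcome and the
untransformed beta value as exposure, so β1 is in trait units per unit beta.
Estimates are pooled by inverse-variance fixed-effect meta-analysis
(weights 1/SE²; pooled SE (Σw)^{−1/2}; Cochran's Q on k−1 df), hierarchically:
the two Chinese sample sets first, then all four base strata. For a
fixed-effect model the two-stage pooled effect and SE are algebraically
identical to one-stage pooling; heterogeneity is computed over the four base
strata, which reproduces the published heterogeneity P-values (pooling the
Chinese-stage result as a single pseudo-stratum does not). Significance is
BH-FDR < 0.05.

Pooled P-values use the Normal approximation on effect/SE, the convention of
fixed-effect meta-analysis software. At stratum sample sizes around 100 the
stratum t-distributions have slightly heavier tails, so meta-level P-values
are mildly anti-conservative (empirically ~0.057 at nominal 0.05 under the
null); the per-stratum P-values are exact t and calibrate at 0.050. The FDR
step operates on the meta P-values, as in the emulated analysis.

Temporal direction is assessed two ways. The cross-lagged panel model is the
saturated two-wave path model on residualized, Z-standardized variables:
each follow-up variable is regressed on both baseline variables, so the
cross paths c_xy (baseline X → follow-up Y) and c_yx are multiple-regression
coefficients; for this saturated model the OLS solution coincides with the
SEM maximum-likelihood fit (asserted against a numerical MVN likelihood
optimization in the tests) and the comparative fit index is 1 by
construction (reported for completeness against the independence baseline).
Path SEs are OLS SEs; an `ml_se` flag rescales by √(df/n) for the ML
convention. One published structural-equation listing contains an apparent
copy error (the same follow-up variable regressed twice); the standard CLPM
form — each follow-up variable on both baseline variables — is implemented.

Bidirectional MR: forward MR instruments each hit CpG with its top cis-SNP
(smallest meta P within a closed 1 Mb window), excluding nonsignificant
instruments (P > 0.05), SNPs flagged inside the probe-binding sequence, and
SNPs associated with the trait after adjusting for the CpG (P < 0.05, the
pleiotropy/collider screen). The causal estimate is the signed Wald ratio
eff(trait~SNP)/eff(CpG~SNP); its delta-method SE is
√((e_b²/e_c²)(s_b²/e_b² + s_c²/e_c²)). The published formula is written in
squared form, which cannot carry sign; the signed ratio with the same
magnitude is used because the predicted-vs-observed correlation test
requires signed values. Backward MR uses a polygenic risk score
(allele-harmonized weighted dosage sum; missing dosages mean-imputed per
SNP) as instrument for the trait and mirrors the same ratio per CpG.
Observed effects for the backward comparison are regressions of CpG on the
trait with the discovery covariates — the only dimensionally consistent
reading. The methylation risk score is the Z-standardized weighted sum of
hit-CpG betas, weighted by the trans-ethnic meta effects (weights are
configurable; the source analysis does not state its weighting).

## QC conventions

- Background correction subtracts, per sample, the 5th percentile (linear
  interpolation) of negative-control signals from M and U, floored at zero.
  The array-channel-aware variant is out of scope; this preserves the
  method's intent in a channel-free data model.
- Detection P is the upper-tail Normal probability of M+U under the
  per-sample negative-control distribution, applied after background
  correction.
- The sex-check statistic is log2 median(chrY total) − log2 median(chrX
  total); orientation chosen so males (Y present) sit near 0, above the −2
  cut.
- Sample missingness and probe-failure rules are strict inequalities
  (exactly 5% is retained).
- Cross-reactive and SNP-affected probes are flagged and retained, never
  dropped; reports carry the flags.
- Quantile normalization is applied on the beta scale within each stated
  sample group (the scale is not specified by the source; beta-scale is the
  simpler choice and is documented here). Ties receive the mean reference
  value of their tie block.
- The full QC order is: background correction → detection P → sample
  filters → probe filters → quantile normalization → beta.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes; its
defaults are the study conditions.

Design: four strata (MEC Chinese, iOmics Chinese, iOmics Malay, iOmics
Indian), `n_per_stratum` samples each, two visits with follow-up time
Normal(6.8, 1.39) years truncated at 1. BMI per sample is a stratum mean
(23.5/23.5/26.5/25.5 kg/m²) plus small age and sex terms, a genetic
component from 20 trait SNPs (effects Normal(0, 0.35 kg/m² per allele),
about 6% of BMI variance — strong enough that the PRS is a valid instrument
at the scaled-down n, as the emulated analysis assumes of its external-GWAS
PRS), and Gaussian noise scaled so the non-demographic SD is 4 kg/m². WC is
30 + 2.3·BMI + Normal(0, 4) cm.

Methylation: each probe has a baseline level Uniform(0.15, 0.85), a linear
cell term (loadings Normal(0, 0.05) on mean-centered Dirichlet cell
proportions, six types at realistic blood means), a batch term (loading ×
latent per-sample batch score × 0.01), an optional cis-mQTL term (±0.03 beta
per allele — a strong top-mQTL at ~25% of probe variance; larger values make
the collider-based pleiotropy screen reject nearly all instruments, which
the emulated analysis does not show), a standardized residual process
scaled by s, and Normal(0, 0.02) measurement noise, clipped to (0.001,
0.999). One hundred twenty designated reference probes instead carry exact
cell-mixture values R·p for the deconvolution.

Temporal structure: the residual process of a causal probe is cross-lagged
on the standardized non-demographic BMI deviation z,

    r_1 = a_y·r_0 + c_xy·z_0 + e,   z_1 = a_x·z_0 + e',

with a_x = a_y = 0.6, c_xy = ±0.3, baseline correlation ρ0 = c_xy, and
innovation variances chosen to keep unit variances. The methylation scale is
s = effect_scale·σ_V / c_xy, so `effect_scale_bmi_to_cpg` (default 0.002) is
the beta-units-per-kg/m² effect of baseline BMI. Because methylation is
generated downstream of BMI, the only well-defined "true EWAS effect" for
the trait-on-beta regression is the population partial regression slope,

    slope = s·a_x·(a_y·ρ0 + c_xy)·σ_V / (s² + σ_noise² + σ_mQTL²),

recorded per probe in the truth table (≈ ±24–28 kg/m² per unit beta at
defaults, the magnitude the emulated study reports). The WC slope is 2.3×
the BMI slope. mQTLs are assigned to causal probes first so association hits
carry cis instruments for forward MR. IL-6 is generated downstream of the
causal-probe composite (cross path 0.3); TNF-α and 151 of 155 metabolites
are autoregressive noise.

Corruption is explicit configuration, not emergent: named (or counted)
samples get 8% of probes collapsed to background signal (missingness
failure) or a flipped reported sex, and the truth table lists them, giving
QC a deterministic test surface. Female chrY probes simulate at 1/16 of full
signal (a cross-hybridization level detectable above background) because at
a scaled-down probe count background-level chrY would push every female over
the 5% missingness rule, which cannot happen on a full-size array.

What the generator does not emulate: realistic LD beyond single cis loci,
channel/dye structure and IDAT-level artifacts, probe-type (I/II) chemistry
differences, non-Gaussian phenotype tails, and cell-proportion–phenotype
confounding. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed generative model, not robustness to
every artifact of real arrays.

## Problem sizes and numerical choices

Verification runs use scaled-down sizes chosen as the package's own test
conditions: type-I calibration on 10,000 null CpGs at n = 100/stratum
(per-stratum t P-values calibrate at 0.050); FDR cleanliness over 20 seeds;
effect recovery at n = 500/stratum over 20 seeds on a 600-probe array —
at only ~150 probes the 120 reference probes dominate the array and
quantile normalization couples them to the analytic probes, biasing
deconvolution; 600 probes restores a realistic minority share, and the mean
relative bias is within a few percent; CLPM direction at n = 1,000
(FDR-significant forward paths at ≥ 80% of causal probes, reverse at the
null rate) and path accuracy ±0.01 at n = 100,000; forward MR at the
genotyped-subset scale n ≈ 208; backward MR at n = 600. The Wald-ratio SE is
checked against a 10⁶-draw Monte-Carlo oracle using the robust IQR/1.349
bulk scale, since the ratio distribution is heavy-tailed even at |z| ≈ 5.

Other numerical conventions: PCA signs are fixed by making each component's
largest-magnitude loading positive; collinear covariates are dropped by
pivoted-QR rank detection with a warning (e.g. the six cell fractions plus
intercept, or all-nonsmoker strata); constant probes yield flagged NaN
estimates rather than errors; locus clumping for the conditional analysis
uses 500 kb single-linkage (the novelty window; no locus definition is
given by the source) with a Bonferroni 0.05/n_loci secondary-signal
threshold and a |r| > 0.99 collinearity guard; the cis window is a closed
±1 Mb interval on transcript start positions; novelty requires strictly
more than 500 kb; sign ties (effect exactly 0) are excluded from
concordance counts; expression pre-processing replaces latent-factor
(PEER-style) correction with the top five expression PCs, documented as a
surrogate, with the count configurable; below-detection-limit biomarker
values are imputed as 0.9 × the minimum observed value.

## Known limitations

- The CLPM is two-wave and observed-variable only; no latent growth or >2
  wave support.
- Random-effects meta-analysis is not implemented (fixed-effect only, per
  the analysis being reproduced).
- Forward MR is single-instrument Wald ratio per CpG; multi-SNP estimators
  (IVW-MR, MR-Egger, weighted median) are out of scope.
- The Houseman deconvolution ships with a synthetic reference; real 450K/
  EPIC references are accepted as TSV but none is bundled.
- VCF support covers dosage (DS) records only.
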