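"""Temporal direction of the BMI-methylation association via CLPM.

The generator builds a cross-lagged structure in which baseline BMI drives
follow-up methylation at the causal probes (and not the reverse). The
two-wave cross-lagged panel model should find significant forward paths
(baseline BMI -> follow-up CpG) and null reverse paths.
"""

import warnings

import pandas as pd

from adipoewas import (SynthConfig, clpm_scan, control_probe_pcs,
                       houseman_deconvolve, run_qc, simulate_study)

warnings.filterwarnings("ignore")

bundle = simulate_study(SynthConfig(n_per_stratum=150, n_probes=200, seed=8,
                                    frac_causal_bmi_to_cpg=0.2))
betas, covs = {}, {}
for visit in ("base", "fu"):
    bm, _ = run_qc(bundle.intensities[visit],
                   bundle.pheno(visit).reset_index())
    pcs = control_probe_pcs(bundle.intensities[visit].controls[bm.samples],
                            k=5).scores
    cells = houseman_deconvolve(bm, bundle.cell_reference).drop(columns="sum")
    betas[visit], covs[visit] = bm, cells.join(pcs)

truth = bundle.truth["probes"]
causal = [c for c in truth.index[truth["is_causal"]]
          if c in betas["base"].beta.index and c in betas["fu"].beta.index]
ph_b, ph_f = bundle.pheno("base"), bundle.pheno("fu")
common = betas["base"].samples.intersection(betas["fu"].samples)
sexf = lambda ph: pd.DataFrame(
    {"age": ph.loc[common, "age"],
     "sex": (ph.loc[common, "sex"] == "M").astype(float)}, index=common)

scan = clpm_scan(betas["base"].beta.loc[causal, common],
                 betas["fu"].beta.loc[causal, common],
                 ph_b.loc[common, "BMI"], ph_f.loc[common, "BMI"],
                 sexf(ph_b), sexf(ph_f),
                 covs["base"].loc[common], covs["fu"].loc[common])

fwd = (scan["p_fdr_c_xy"] < 0.05).sum()
rev = (scan["p_fdr_c_yx"] < 0.05).sum()
print(scan[["cpg", "c_xy", "p_fdr_c_xy", "c_yx", "p_fdr_c_yx", "cfi"]]
      .head(8).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
print(f"Of {len(scan)} truly BMI-responsive CpGs: {fwd} show a significant")
print(f"BMI -> methylation path (c_xy, FDR < 0.05) and {rev} show the")
print("reverse path - the temporal signature of BMI driving methylation.")
print("CFI = 1 because the two-wave path model is saturated.")
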