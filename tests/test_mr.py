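"""Mendelian randomization: Wald ratios, instruments, risk scores."""

import numpy as np
import pandas as pd
import pytest

from adipoewas import (Genotypes, SynthConfig, backward_mr, compute_mrs,
                       compute_prs, forward_mr, select_cis_iv, simulate_study,
                       wald_ratio)
from adipoewas.mr import harmonize_effect


class TestWaldRatio:
    def test_worked_example_with_monte_carlo_oracle(self, rng):
        pred, se = wald_ratio(0.3, 0.1, 0.5, 0.1)
        assert pred == pytest.approx(0.6)
        assert se == pytest.approx(
            np.sqrt(0.36 * (0.01 / 0.09 + 0.01 / 0.25)), rel=1e-12)
        # Monte-Carlo oracle over 10^6 draws; the ratio is heavy-tailed, so
        # the bulk scale is estimated robustly (IQR / 1.349), which the
        # delta-method SE approximates
        from scipy import stats
        num = rng.normal(0.3, 0.1, 1_000_000)
        den = rng.normal(0.5, 0.1, 1_000_000)
        draws = num / den
        mc = (np.percentile(draws, 75) - np.percentile(draws, 25)) \
            / (2 * stats.norm.ppf(0.75))
        assert se == pytest.approx(mc, rel=0.02)

    def test_noiseless_inputs(self):
        pred, se = wald_ratio(0.8, 0.0, 0.4, 0.0)
        assert pred == pytest.approx(2.0) and se == 0.0

    def test_sign_carried_by_ratio(self):
        pred, _ = wald_ratio(-0.3, 0.1, 0.5, 0.1)
        assert pred == pytest.approx(-0.6)
        pred, _ = wald_ratio(0.3, 0.1, -0.5, 0.1)
        assert pred == pytest.approx(-0.6)

    def test_zero_outcome_effect_limit_form(self):
        pred, se = wald_ratio(0.0, 0.2, 0.5, 0.1)
        assert pred == 0.0 and se == pytest.approx(0.4)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.3, 0.1, 0.0, 0.1)

    def test_se_accuracy_against_oracle_when_instruments_strong(self, rng):
        # |eff/SE| >= 3 on both axes: delta SE within 2% of the Monte-Carlo
        # bulk scale (robust IQR spread of the simulated ratio)
        from scipy import stats
        for eo, so, ee, se_e in ((0.5, 0.08, 1.0, 0.15), (-1.2, 0.3, 0.6, 0.1)):
            _, se = wald_ratio(eo, so, ee, se_e)
            draws = rng.normal(eo, so, 10**6) / rng.normal(ee, se_e, 10**6)
            mc = (np.percentile(draws, 75) - np.percentile(draws, 25)) \
                / (2 * stats.norm.ppf(0.75))
            assert se == pytest.approx(mc, rel=0.02)


class TestRiskScores:
    def _geno(self):
        dos = pd.DataFrame([[2.0, 1.0], [0.0, 1.0], [1.0, 2.0]],
                           index=["r1", "r2", "r3"], columns=["s1", "s2"])
        coords = pd.DataFrame({"chr": ["1"] * 3, "pos": [1, 2, 3],
                               "effect_allele": ["A", "A", "A"],
                               "other_allele": ["G", "G", "G"]},
                              index=["r1", "r2", "r3"])
        return Genotypes(dosages=dos, coords=coords)

    def test_single_snp_prs(self):
        w = pd.DataFrame({"snp": ["r1"], "effect_allele": ["A"], "weight": [1.0]})
        prs = compute_prs(self._geno(), w)
        assert prs["s1"] == 2.0 and prs["s2"] == 1.0

    def test_allele_flip_harmonization_identity(self):
        # stating the other allele as effect allele scores 2 - dosage
        w_a = pd.DataFrame({"snp": ["r1"], "effect_allele": ["A"], "weight": [1.0]})
        w_g = pd.DataFrame({"snp": ["r1"], "effect_allele": ["G"], "weight": [-1.0]})
        a = compute_prs(self._geno(), w_a)
        g = compute_prs(self._geno(), w_g)
        np.testing.assert_allclose(a - g, 2.0)  # differ by the constant 2w

    def test_three_snp_hand_computed(self):
        w = pd.DataFrame({"snp": ["r1", "r2", "r3"],
                          "effect_allele": ["A", "G", "A"],
                          "weight": [0.5, 1.0, -2.0]})
        prs = compute_prs(self._geno(), w)
        # s1: 0.5*2 + 1.0*(2-0) + (-2)*1 = 1.0 ; s2: 0.5 + 1.0 - 4 = -2.5
        assert prs["s1"] == pytest.approx(1.0)
        assert prs["s2"] == pytest.approx(-2.5)

    def test_no_overlap_is_an_error(self):
        w = pd.DataFrame({"snp": ["zz"], "effect_allele": ["A"], "weight": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            compute_prs(self._geno(), w)

    def test_mrs_single_cpg_is_standardized_beta(self, rng):
        beta = pd.DataFrame(rng.uniform(0, 1, (1, 30)), index=["cg1"])
        mrs = compute_mrs(beta, pd.Series({"cg1": 1.0}))
        b = beta.iloc[0]
        np.testing.assert_allclose(mrs, (b - b.mean()) / b.std(ddof=1))

    def test_mrs_hand_computed_three_cpgs(self, rng):
        beta = pd.DataFrame(rng.uniform(0, 1, (3, 20)),
                            index=["a", "b", "c"])
        w = pd.Series({"a": 2.0, "b": -1.0, "c": 0.5})
        mrs = compute_mrs(beta, w)
        raw = 2 * beta.loc["a"] - beta.loc["b"] + 0.5 * beta.loc["c"]
        np.testing.assert_allclose(mrs, (raw - raw.mean()) / raw.std(ddof=1))

    def test_mrs_degenerate_weights_error(self, rng):
        beta = pd.DataFrame(rng.uniform(0, 1, (2, 10)), index=["a", "b"])
        with pytest.raises(ValueError, match="zero"):
            compute_mrs(beta, pd.Series({"a": 0.0, "b": 0.0}))
        with pytest.raises(ValueError, match="present"):
            compute_mrs(beta, pd.Series({"x": 1.0, "y": 1.0, "z": 1.0}))

    def test_harmonize_flip_involution(self):
        ss = pd.DataFrame({"snp": ["r1"], "effect_allele": ["G"],
                           "other_allele": ["A"], "beta": [0.4], "se": [0.1]})
        b, s = harmonize_effect("r1", "A", ss)
        assert b == pytest.approx(-0.4)
        b2, _ = harmonize_effect("r1", "G", ss)
        assert b2 == pytest.approx(0.4)


class TestInstrumentSelection:
    def _world(self, seed=3):
        cfg = SynthConfig(n_per_stratum=150, n_probes=80, seed=seed,
                          frac_causal_bmi_to_cpg=0.15, frac_mqtl=0.15)
        return simulate_study(cfg)

    def _covars(self, b):
        return pd.DataFrame(
            {f"cell_{c}": b.truth["samples"][f"cell_{c}"]
             for c in b.cell_reference.cell_types})

    def test_true_mqtl_selected_with_correct_sign(self):
        b = self._world()
        truth = b.truth["probes"]
        mqtl = truth[truth["is_mqtl"]]
        man = b.intensities["fu"].manifest
        hits = pd.DataFrame({"cpg": mqtl.index,
                             "chr": man.loc[mqtl.index, "chr"].to_numpy(),
                             "pos": man.loc[mqtl.index, "pos"].to_numpy()})
        iv = select_cis_iv(hits, b.genotypes, b.beta_true["fu"],
                           b.pheno("fu"), self._covars(b))
        merged = iv.merge(mqtl.reset_index(), left_on="cpg",
                          right_on="probe_id")
        picked = merged[merged["snp"].notna()]
        correct = (picked["snp"] == picked["mqtl_snp"])
        assert correct.mean() >= 0.9
        same_sign = np.sign(picked.loc[correct, "eff_cpg_snp"]) == \
            np.sign(picked.loc[correct, "mqtl_effect"])
        assert same_sign.mean() >= 0.95

    def test_window_boundary_closed(self):
        b = self._world()
        man = b.intensities["fu"].manifest
        cpg = man.index[0]
        snp = b.genotypes.coords.index[0]
        coords = b.genotypes.coords.copy()
        coords.loc[:, "chr"] = "99"  # push everything out of range
        coords.loc[snp, "chr"] = man.loc[cpg, "chr"]
        coords.loc[snp, "pos"] = int(man.loc[cpg, "pos"]) + 1_000_000
        gt = Genotypes(dosages=b.genotypes.dosages, coords=coords)
        hits = pd.DataFrame({"cpg": [cpg], "chr": [man.loc[cpg, "chr"]],
                             "pos": [man.loc[cpg, "pos"]]})
        iv = select_cis_iv(hits, gt, b.beta_true["fu"], b.pheno("fu"),
                           self._covars(b))
        assert iv.loc[0, "snp"] == snp  # exactly 1 Mb away: included
        coords.loc[snp, "pos"] += 1
        iv = select_cis_iv(hits, Genotypes(dosages=b.genotypes.dosages,
                                           coords=coords),
                           b.beta_true["fu"], b.pheno("fu"), self._covars(b))
        assert iv.loc[0, "exclusion_reason"] == "no_cis_snp"

    def test_monomorphic_snp_not_a_candidate(self):
        b = self._world()
        man = b.intensities["fu"].manifest
        cpg = man.index[0]
        coords = b.genotypes.coords.copy()
        coords.loc[:, "chr"] = "99"
        snp = coords.index[0]
        coords.loc[snp, "chr"] = man.loc[cpg, "chr"]
        coords.loc[snp, "pos"] = int(man.loc[cpg, "pos"])
        dos = b.genotypes.dosages.copy()
        dos.loc[snp] = 1.0  # constant dosage
        iv = select_cis_iv(pd.DataFrame({"cpg": [cpg],
                                         "chr": [man.loc[cpg, "chr"]],
                                         "pos": [man.loc[cpg, "pos"]]}),
                           Genotypes(dosages=dos, coords=coords),
                           b.beta_true["fu"], b.pheno("fu"), self._covars(b))
        assert iv.loc[0, "exclusion_reason"] == "no_cis_snp"

    def test_probe_binding_flag_excludes(self):
        b = self._world()
        truth = b.truth["probes"]
        mqtl = truth[truth["is_mqtl"]].head(3)
        man = b.intensities["fu"].manifest
        coords = b.genotypes.coords.copy()
        coords["in_probe_binding"] = True
        iv = select_cis_iv(
            pd.DataFrame({"cpg": mqtl.index,
                          "chr": man.loc[mqtl.index, "chr"].to_numpy(),
                          "pos": man.loc[mqtl.index, "pos"].to_numpy()}),
            Genotypes(dosages=b.genotypes.dosages, coords=coords),
            b.beta_true["fu"], b.pheno("fu"), self._covars(b))
        kept = iv[iv["p"] < 0.05]
        assert (kept["exclusion_reason"] == "probe_binding").all()


class TestBidirectionalMr:
    @pytest.fixture(scope="class")
    def world(self):
        cfg = SynthConfig(n_per_stratum=150, n_probes=100, seed=17,
                          frac_causal_bmi_to_cpg=0.2, frac_mqtl=0.2)
        b = simulate_study(cfg)
        covars = pd.DataFrame(
            {f"cell_{c}": b.truth["samples"][f"cell_{c}"]
             for c in b.cell_reference.cell_types})
        return b, covars

    def test_forward_mr_null_in_bmi_to_cpg_world(self, world):
        """Methylation does not cause BMI here: no causal calls, r ~ 0."""
        b, covars = world
        truth = b.truth["probes"]
        causal = truth[truth["is_causal"] & truth["is_mqtl"]]
        man = b.intensities["fu"].manifest
        hits = pd.DataFrame({"cpg": causal.index,
                             "chr": man.loc[causal.index, "chr"].to_numpy(),
                             "pos": man.loc[causal.index, "pos"].to_numpy()})
        iv = select_cis_iv(hits, b.genotypes, b.beta_true["fu"],
                           b.pheno("fu"), covars)
        ewas_meta = pd.DataFrame({"cpg": causal.index,
                                  "effect": truth.loc[causal.index,
                                                      "ewas_slope_bmi"]})
        table, summary = forward_mr(iv, b.sumstats, ewas_meta,
                                    b.genotypes.coords)
        assert summary["n_causal"] == 0
        if summary["n"] >= 3:
            assert abs(summary["r"]) < 0.8  # no systematic agreement

    def test_backward_mr_recovers_bmi_to_cpg_direction(self, world):
        b, covars = world
        truth = b.truth["probes"]
        causal = truth.index[truth["is_causal"]]
        weights = b.sumstats[b.sumstats["p"] < 5e-8].rename(
            columns={"beta": "weight"})[["snp", "effect_allele", "weight"]]
        prs = compute_prs(b.genotypes, weights)
        table, summary = backward_mr(prs, b.beta_true["fu"], b.pheno("fu"),
                                     covars, cpgs=list(causal))
        assert summary["r"] > 0.4
        assert summary["prs_trait_p"] < 0.05

    def test_single_snp_backward_equals_forward_algebra(self, world):
        """With a one-SNP score both estimators reduce to the same ratio."""
        b, covars = world
        snp = b.sumstats.sort_values("p")["snp"].iloc[0]
        w = pd.DataFrame({"snp": [snp], "effect_allele": ["A"], "weight": [1.0]})
        prs = compute_prs(b.genotypes, w)
        np.testing.assert_allclose(prs.to_numpy(),
                                   b.genotypes.dosages.loc[snp].to_numpy())
        cpg = b.truth["probes"].index[b.truth["probes"]["is_causal"]][0]
        table, _ = backward_mr(prs, b.beta_true["fu"], b.pheno("fu"), covars,
                               cpgs=[cpg])
        # oracle: direct ratio of the two meta-analyzed slopes on the dosage
        from adipoewas.mr import _meta_assoc_per_stratum, _stratum_blocks
        samples = b.beta_true["fu"].columns.intersection(prs.index)
        blocks = _stratum_blocks(b.pheno("fu"), covars, samples)
        ys = [b.beta_true["fu"].loc[cpg, s].to_numpy() for s, _ in blocks]
        xs = [prs[s].to_numpy() for s, _ in blocks]
        Cs = [C for _, C in blocks]
        m_cpg = _meta_assoc_per_stratum(ys, xs, Cs)
        ys2 = [b.pheno("fu").loc[s, "BMI"].to_numpy() for s, _ in blocks]
        m_bmi = _meta_assoc_per_stratum(ys2, xs, Cs)
        expected, _ = wald_ratio(m_cpg.effect, m_cpg.se, m_bmi.effect, m_bmi.se)
        assert table.loc[0, "predicted_eff"] == pytest.approx(expected, rel=1e-10)

    def test_sumstats_allele_flip_corrected(self, world):
        b, covars = world
        truth = b.truth["probes"]
        causal = truth[truth["is_causal"] & truth["is_mqtl"]].head(3)
        man = b.intensities["fu"].manifest
        hits = pd.DataFrame({"cpg": causal.index,
                             "chr": man.loc[causal.index, "chr"].to_numpy(),
                             "pos": man.loc[causal.index, "pos"].to_numpy()})
        iv = select_cis_iv(hits, b.genotypes, b.beta_true["fu"],
                           b.pheno("fu"), covars)
        flipped = b.sumstats.copy()
        flipped["effect_allele"], flipped["other_allele"] = \
            flipped["other_allele"].copy(), flipped["effect_allele"].copy()
        flipped["beta"] = -flipped["beta"]
        ewas_meta = pd.DataFrame({"cpg": causal.index, "effect": 0.0})
        t1, _ = forward_mr(iv, b.sumstats, ewas_meta, b.genotypes.coords)
        t2, _ = forward_mr(iv, flipped, ewas_meta, b.genotypes.coords)
        ok = t1["predicted_eff"].notna()
        np.testing.assert_allclose(t1.loc[ok, "predicted_eff"],
                                   t2.loc[ok, "predicted_eff"], rtol=1e-12)
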