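"""Intensity-level QC: background, detection, filters, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipoewas import (QcThresholds, background_correct, compute_beta,
                       detection_pvalues, filter_probes, filter_samples,
                       quantile_normalize, run_qc)
from adipoewas.qc import infer_sex

from conftest import make_intensity


class TestBackgroundCorrect:
    def test_zero_negative_controls_leave_data_unchanged(self):
        data = make_intensity([[100.0]], [[50.0]], neg=np.zeros((3, 1)))
        out = background_correct(data)
        assert out.M.iloc[0, 0] == 100.0 and out.U.iloc[0, 0] == 50.0

    def test_floor_at_zero_when_background_exceeds_signal(self):
        data = make_intensity([[50.0]], [[50.0]], neg=np.full((3, 1), 100.0))
        out = background_correct(data)
        assert out.M.iloc[0, 0] == 0.0

    def test_fifth_percentile_of_negative_controls(self):
        # controls 10..100: 5th percentile (linear interpolation) = 14.5,
        # cross-checked by sorting: 10 + 0.45*(20-10)
        neg = np.arange(10.0, 101.0, 10.0)[:, None]
        assert np.quantile(np.sort(neg.ravel()), 0.05) == pytest.approx(14.5)
        data = make_intensity([[114.5]], [[114.5]], neg=neg)
        out = background_correct(data)
        assert out.M.iloc[0, 0] == pytest.approx(100.0)

    def test_no_negative_controls_is_an_error(self):
        data = make_intensity([[1.0]], [[1.0]])
        data.controls["control_type"] = "STAINING"
        with pytest.raises(ValueError, match="NEGATIVE"):
            background_correct(data)


class TestDetectionPvalues:
    def test_total_at_background_mean_gives_half(self, rng):
        neg = rng.normal(100, 10, (50, 1))
        mu = neg.mean()
        data = make_intensity([[mu / 2]], [[mu / 2]], neg=neg)
        detp = detection_pvalues(data)
        assert detp.iloc[0, 0] == pytest.approx(0.5)

    def test_large_signal_gives_vanishing_p(self):
        neg = np.tile(np.array([90.0, 100.0, 110.0])[:, None], (1, 1))
        data = make_intensity([[1e6]], [[1e6]], neg=neg)
        assert detection_pvalues(data).iloc[0, 0] < 1e-300

    def test_normal_upper_tail_value(self):
        # background N(100, 10); total 119.6 -> upper tail ~ 0.025
        neg = np.array([[90.0], [100.0], [110.0]])
        mu, sd = neg.mean(), neg.std(ddof=1)
        data = make_intensity([[59.8]], [[59.8]], neg=neg)
        expected = stats.norm.sf((119.6 - mu) / sd)
        assert detection_pvalues(data).iloc[0, 0] == pytest.approx(expected)
        # independent CDF evaluation at the canonical (100, 10) parameters
        assert stats.norm.sf((119.6 - 100) / 10) == pytest.approx(0.025, abs=2e-4)

    def test_monotone_nonincreasing_in_total_signal(self, rng):
        neg = rng.normal(80, 10, (30, 1))
        totals = np.linspace(10, 400, 10)
        data = make_intensity(totals[:, None] / 2, totals[:, None] / 2,
                              neg=np.tile(neg, (1, 1)))
        col = detection_pvalues(data).iloc[:, 0].to_numpy()
        assert np.all(np.diff(col) <= 1e-12)

    def test_zero_sd_warns_and_steps(self):
        neg = np.full((3, 1), 50.0)
        data = make_intensity([[100.0], [10.0]], [[100.0], [10.0]], neg=neg)
        with pytest.warns(UserWarning, match="zero negative-control SD"):
            detp = detection_pvalues(data)
        assert detp.iloc[0, 0] == 0.0 and detp.iloc[1, 0] == 1.0


class TestSampleFilter:
    def _data(self, n_probes=100, n_samples=4):
        rng = np.random.default_rng(0)
        M = rng.uniform(4000, 6000, (n_probes, n_samples))
        U = rng.uniform(4000, 6000, (n_probes, n_samples))
        return make_intensity(M, U, neg=rng.normal(60, 10, (20, n_samples)))

    def test_missingness_above_threshold_excludes_with_reason(self):
        data = self._data()
        detp = pd.DataFrame(0.0, index=data.probes, columns=data.samples)
        detp.iloc[:6, 0] = 1.0  # 6% of probes fail in sample s0
        filtered, report = filter_samples(data, detp)
        assert report.sample_table.loc["s0", "reason"] == "missingness"
        assert "s0" not in filtered.samples
        # 5% exactly is not an exclusion (rule is strictly greater)
        detp.iloc[:, :] = 0.0
        detp.iloc[:5, 1] = 1.0
        _, report = filter_samples(data, detp)
        assert not report.sample_table.loc["s1", "excluded"]

    def test_sexcheck_diff_zero_reports_male(self):
        rng = np.random.default_rng(1)
        manifest = pd.DataFrame({"chr": ["1"] * 40 + ["X"] * 5 + ["Y"] * 5,
                                 "pos": np.arange(50) * 1000 + 1})
        manifest.index = [f"p{i}" for i in range(50)]
        M = rng.uniform(4000, 6000, (50, 2))
        data = make_intensity(M, M, neg=rng.normal(60, 10, (10, 2)),
                              manifest=manifest)
        sexinfo = infer_sex(data)
        assert (sexinfo["sexcheck_diff"].abs() < 1).all()
        assert (sexinfo["inferred_sex"] == "M").all()

    def test_sex_mismatch_excluded(self):
        rng = np.random.default_rng(2)
        manifest = pd.DataFrame({"chr": ["1"] * 40 + ["X"] * 5 + ["Y"] * 5,
                                 "pos": np.arange(50) * 1000 + 1})
        manifest.index = [f"p{i}" for i in range(50)]
        M = rng.uniform(4000, 6000, (50, 1))
        M[45:] /= 8.0  # chrY at 1/8 -> diff = -3 => inferred female
        data = make_intensity(M, M, neg=rng.normal(60, 10, (10, 1)),
                              manifest=manifest)
        detp = pd.DataFrame(0.0, index=data.probes, columns=data.samples)
        sheet = pd.DataFrame({"sample_id": ["s0"], "sex": ["M"]})
        _, report = filter_samples(data, detp, sheet)
        assert report.sample_table.loc["s0", "reason"] == "sex_mismatch"


class TestProbeFilter:
    def test_boundary_and_categories(self):
        # 10 probes x 20 samples: p0 fails detP in 30%, p1 beadcount in 10%,
        # p2/p3 on chrX; p4 fails detP in exactly 5% (retained)
        n, s = 10, 20
        rng = np.random.default_rng(3)
        manifest = pd.DataFrame({"chr": ["1"] * 2 + ["X", "X"] + ["1"] * 6,
                                 "pos": np.arange(n) * 1000 + 1})
        manifest.index = [f"p{i}" for i in range(n)]
        manifest.loc["p5", "chr"] = "1"
        bead = np.full((n, s), 10)
        bead[1, :2] = 1  # 10% of samples below 3
        data = make_intensity(rng.uniform(1000, 2000, (n, s)),
                              rng.uniform(1000, 2000, (n, s)),
                              beadcount=bead,
                              neg=rng.normal(60, 10, (5, s)), manifest=manifest)
        detp = pd.DataFrame(0.0, index=data.probes, columns=data.samples)
        detp.iloc[0, :6] = 1.0   # p0: 30% fail
        detp.iloc[4, :1] = 1.0   # p4: 5% exactly -> retained
        filtered, report = filter_probes(data, detp)
        t = report.probe_table
        assert t.loc["p0", "reason"] == "detection"
        assert t.loc["p1", "reason"] == "beadcount"
        assert t.loc["p2", "reason"] == "sex_chromosome"
        assert t.loc["p3", "reason"] == "sex_chromosome"
        assert not t.loc["p4", "excluded"]
        assert len(filtered.probes) == 6

    def test_sex_chromosome_probe_removed_regardless_of_quality(self):
        manifest = pd.DataFrame({"chr": ["Y", "1"], "pos": [100, 200]},
                                index=["p0", "p1"])
        data = make_intensity([[5000.0], [5000.0]], [[5000.0], [5000.0]],
                              neg=np.random.default_rng(0).normal(60, 10, (5, 1)),
                              manifest=manifest)
        detp = pd.DataFrame(0.0, index=data.probes, columns=data.samples)
        filtered, report = filter_probes(data, detp)
        assert report.probe_table.loc["p0", "reason"] == "sex_chromosome"
        assert list(filtered.probes) == ["p1"]

    def test_flags_retained_not_dropped(self):
        manifest = pd.DataFrame({"chr": ["1", "1"], "pos": [100, 200],
                                 "cross_reactive": [True, False],
                                 "snp_affected": [False, True]},
                                index=["p0", "p1"])
        data = make_intensity([[5000.0], [5000.0]], [[5000.0], [5000.0]],
                              neg=np.zeros((2, 1)) + 50, manifest=manifest)
        detp = pd.DataFrame(0.0, index=data.probes, columns=data.samples)
        filtered, report = filter_probes(data, detp)
        assert len(filtered.probes) == 2
        assert report.probe_table["cross_reactive"].tolist() == [True, False]
        assert report.probe_table["snp_affected"].tolist() == [False, True]


class TestQuantileNormalize:
    def test_two_sample_mean_of_order_statistics(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_identical_samples_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_ties_match_brute_force_oracle(self, rng):
        # brute force: sort each column, average across columns, unsort;
        # ties get the mean reference value over the tie block
        m = pd.DataFrame(rng.integers(0, 4, (5, 4)).astype(float))
        m.columns = list("abcd")
        out = quantile_normalize(m)

        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        for col in m.columns:
            vals = m[col].to_numpy()
            expected = np.empty_like(vals)
            order = np.argsort(vals, kind="mergesort")
            sv = vals[order]
            i = 0
            while i < len(sv):
                j = i
                while j + 1 < len(sv) and sv[j + 1] == sv[i]:
                    j += 1
                expected[order[i:j + 1]] = ref[i:j + 1].mean()
                i = j + 1
            np.testing.assert_allclose(out[col].to_numpy(), expected)

    def test_groups_normalized_separately_and_singleton_warns(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [9.0, 0.0]})
        groups = pd.Series({"a": "g1", "b": "g1", "c": "g2"})
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(m, groups)
        assert out["c"].tolist() == [9.0, 0.0]
        np.testing.assert_allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_grand_mean_of_sorted_columns_conserved(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        out = quantile_normalize(m)
        before = np.sort(m.to_numpy(), axis=0).mean()
        after = np.sort(out.to_numpy(), axis=0).mean()
        assert after == pytest.approx(before, rel=1e-12)


class TestComputeBeta:
    @pytest.mark.parametrize("m,u,expected", [(0, 0, 0.0), (100, 0, 0.5),
                                              (900, 0, 0.9)])
    def test_beta_formula(self, m, u, expected):
        data = make_intensity([[float(m)]], [[float(u)]])
        out = compute_beta(data)
        assert out.beta.iloc[0, 0] == pytest.approx(expected)

    def test_negative_signal_is_an_error(self):
        data = make_intensity([[10.0]], [[10.0]])
        data.M.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            compute_beta(data)


class TestRunQc:
    def test_clean_bundle_has_zero_exclusions(self, bundle):
        data = bundle.intensities["fu"]
        beta, report = run_qc(data, bundle.pheno("fu").reset_index())
        assert len(report.excluded_samples) == 0
        # only sex-chromosome probes drop
        assert set(report.excluded_probes["reason"]) <= {"sex_chromosome"}

    def test_corrupt_samples_excluded_with_exact_reasons(self, corrupt_bundle):
        b = corrupt_bundle
        data = b.intensities["fu"]
        beta, report = run_qc(data, b.pheno("fu").reset_index())
        excl = report.excluded_samples
        miss = set(excl.index[excl["reason"] == "missingness"])
        sexm = set(excl.index[excl["reason"] == "sex_mismatch"])
        assert miss == set(b.truth["params"]["corrupt_missing"])
        assert sexm == set(b.truth["params"]["corrupt_sex"])
        assert len(excl) == len(miss) + len(sexm)

    def test_postqc_invariants(self, bundle):
        data = bundle.intensities["fu"]
        beta, report = run_qc(data, bundle.pheno("fu").reset_index())
        vals = beta.beta.to_numpy()
        assert vals.min() >= 0 and vals.max() < 1
        assert not beta.manifest["chr"].isin(["X", "Y"]).any()

    def test_sample_permutation_equivariance(self, corrupt_bundle):
        from dataclasses import replace

        b = corrupt_bundle
        data = b.intensities["fu"]
        sheet = b.pheno("fu").reset_index()
        perm = list(data.samples[::-1])
        permuted = replace(
            data, M=data.M[perm], U=data.U[perm], beadcount=data.beadcount[perm],
            controls=pd.concat([data.controls[["control_type"]],
                                data.controls[perm]], axis=1))
        beta1, _ = run_qc(data, sheet)
        beta2, _ = run_qc(permuted, sheet)
        pd.testing.assert_frame_equal(beta1.beta, beta2.beta[beta1.beta.columns])

    def test_default_thresholds_in_report_header(self, bundle):
        _, report = run_qc(bundle.intensities["fu"],
                           bundle.pheno("fu").reset_index())
        head = report.thresholds.header()
        for token in ("1e-16", "5%", "beadcount<3", "-2"):
            assert token in head
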