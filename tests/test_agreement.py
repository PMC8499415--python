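import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from gingrec.agreement import (
    adjust_p,
    agreement_report,
    bland_altman,
    bland_altman_plot_data,
    icc,
    threshold_stratify,
)
from gingrec.errors import InputError
from gingrec.synthetic import ExaminerModel, draw_cohort_specs, simulate_deviations


def icc_a1_oracle(x):
    """Independent brute-force ICC(A,1): explicit double loops over cells."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum(
        (x[i][j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


TOY_TABLE = np.array(
    [
        [9.0, 2.0], [6.0, 1.0], [8.0, 4.0],
        [7.0, 1.0], [10.0, 5.0], [6.0, 2.0],
    ]
)


class TestICC:
    def test_identical_columns_perfect(self):
        x = np.tile(np.array([[1.0], [2.5], [3.0], [4.2]]), (1, 3))
        res = icc(x)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)

    def test_toy_table_matches_anova_oracle(self):
        res = icc(TOY_TABLE)
        assert abs(res.estimate - icc_a1_oracle(TOY_TABLE)) < 1e-10
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 0.5, size=(12, 3)) + rng.normal(0, 0.1, size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        ref_row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        res = icc(x)
        assert res.estimate == pytest.approx(ref_row["ICC"], abs=1e-8)
        np.testing.assert_allclose(
            [res.ci_low, res.ci_high], ref_row[ci_col], atol=2e-2
        )  # pingouin rounds its CI bounds to 2 decimals

    def test_noisy_rater_low_icc(self):
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            subj = rng.normal(2.0, 0.5, size=30)
            r2 = subj + rng.normal(0, 5.0, size=30)  # noise sd = 10 x subject sd
            estimates.append(icc(np.column_stack([subj, r2])).estimate)
        assert np.median(estimates) < 0.2

    def test_shift_invariance(self):
        a = icc(TOY_TABLE).estimate
        b = icc(TOY_TABLE + 7.3).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_rater_shift_lowers_absolute_agreement(self):
        rng = np.random.default_rng(9)
        subj = rng.normal(2.0, 0.6, size=15)
        agreeing = np.column_stack([subj, subj + rng.normal(0, 0.05, 15)])
        shifted = agreeing.copy()
        shifted[:, 1] += 1.0
        assert icc(shifted).estimate < icc(agreeing).estimate

    def test_missing_cells_rejected(self):
        x = TOY_TABLE.copy()
        x[0, 0] = np.nan
        with pytest.raises(InputError):
            icc(x)

    def test_too_few_subjects(self):
        with pytest.raises(InputError):
            icc(TOY_TABLE[:2])


class TestBlandAltman:
    def test_zero_differences_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.degenerate and np.isnan(res.p_value)

    def test_hand_computed_example(self):
        b = np.zeros(4)
        a = np.array([-1.0, 1.0, -1.0, 1.0])
        res = bland_altman(a, b)
        sd = np.sqrt(4.0 / 3.0)  # sample sd of (-1,1,-1,1)
        assert res.bias == pytest.approx(0.0, abs=1e-15)
        assert sd == pytest.approx(1.1547005383792515)
        assert res.loa_low == pytest.approx(-1.96 * sd, abs=1e-12)
        assert res.loa_high == pytest.approx(1.96 * sd, abs=1e-12)

    def test_loa_width_invariant(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(2, 0.4, 30), rng.normal(2, 0.4, 30)
        res = bland_altman(a, b)
        sd = np.std(a - b, ddof=1)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * sd, abs=1e-12)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(2, 0.4, 25), rng.normal(2, 0.4, 25)
        assert bland_altman(a, b).bias == -bland_altman(b, a).bias

    def test_bias_ci_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(1, 0.3, 20), rng.normal(1, 0.3, 20)
        res = bland_altman(a, b)
        d = a - b
        t = stats.t.ppf(0.975, 19)
        expect = d.mean() - t * d.std(ddof=1) / np.sqrt(20)
        assert res.bias_ci[0] == pytest.approx(expect, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_loa_monte_carlo_coverage(self):
        rng = np.random.default_rng(99)
        calib = rng.normal(0.0, 0.25, size=5000)
        res = bland_altman(calib, np.zeros(5000))
        fresh = rng.normal(0.0, 0.25, size=10_000)
        coverage = np.mean((fresh >= res.loa_low) & (fresh <= res.loa_high))
        assert abs(coverage - 0.95) <= 0.01

    def test_plot_data(self):
        df = bland_altman_plot_data([1.0, 2.0], [0.5, 2.5])
        np.testing.assert_allclose(df["mean_mm"], [0.75, 2.25])
        np.testing.assert_allclose(df["difference_mm"], [0.5, -0.5])


class TestAdjustP:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_p([0.01]), [0.01])

    def test_bonferroni_times_m(self):
        np.testing.assert_allclose(adjust_p([0.01, 0.04, 0.20]), [0.03, 0.12, 0.60])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_p([0.5, 1.2])

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=10),
        st.sampled_from(["bonferroni", "holm", "fdr_bh"]),
    )
    def test_dominance(self, ps, method):
        adjusted = adjust_p(ps, method=method)
        assert np.all(adjusted >= np.asarray(ps) - 1e-15)
        assert np.all(adjusted <= 1.0)


class TestThresholdStratify:
    def test_empty_stratum(self):
        df = pd.DataFrame({"deviation_mm": [0.1, -0.2], "reference_kappa_per_mm": [-2.0, -3.0]})
        out = threshold_stratify(df, kappa_threshold=1.0)
        assert out["strata"]["below"]["n"] == 0
        assert out["strata"]["above"]["n"] == 2

    def test_below_threshold_more_variable(self):
        wins = 0
        for seed in range(100):
            specs = draw_cohort_specs(60, seed=seed)
            devs = simulate_deviations(specs, ExaminerModel(), seed=seed)
            cej = devs[devs["landmark"] == "CEJ"]
            out = threshold_stratify(cej, kappa_threshold=1.0)
            below, above = out["strata"]["below"], out["strata"]["above"]
            if below["n"] and above["n"]:
                wins += below["median_abs_deviation_mm"] > above["median_abs_deviation_mm"]
        assert wins >= 95

    def test_cej_fraction_below_one_near_half(self):
        # draw distribution is matched to a median of 0.99: roughly half of
        # sites fall below the 1 mm^-1 threshold (report-style check, loose)
        specs = draw_cohort_specs(600, seed=17)
        frac = np.mean([abs(s.cej_kappa) < 1.0 for s in specs])
        assert 0.35 < frac < 0.65

    def test_missing_columns(self):
        with pytest.raises(InputError):
            threshold_stratify(pd.DataFrame({"x": [1.0]}))


class TestAgreementReport:
    def test_full_report_structure(self):
        rng = np.random.default_rng(12)
        auto = rng.uniform(1.0, 3.0, size=20)
        rows = [
            {"site_id": f"s{i}", "method": "automated", "round": 0, "depth_mm": auto[i], "status": "ok"}
            for i in range(20)
        ]
        for e in (1, 2, 3):
            for r in (1, 2):
                for i in range(20):
                    rows.append(
                        {
                            "site_id": f"s{i}",
                            "method": f"examiner{e}",
                            "round": r,
                            "depth_mm": auto[i] + rng.normal(0, 0.1),
                            "status": "ok",
                        }
                    )
        report = agreement_report(pd.DataFrame(rows))
        assert len(report["bland_altman"]) == 6  # 3 examiners x 2 rounds
        assert set(report["icc"]["inter_examiner"]) == {"round1", "round2"}
        assert set(report["icc"]["intra_examiner"]) == {"examiner1", "examiner2", "examiner3"}
        for block in report["bland_altman"].values():
            assert block["p_adjusted"] >= block["p_value"] - 1e-15
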