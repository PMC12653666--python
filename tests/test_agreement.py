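"""Statistics battery: worked examples, brute-force oracles, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pendulumtest.agreement import (
    PairedMeasurements,
    between_limb_effect,
    bland_altman,
    icc_consistency,
    iqr_filter,
    paired_limb_comparison,
    shapiro_gate,
    spearman_mas,
    study_report,
)


def brute_force_icc_consistency(values):
    """Independent ANOVA oracle: explicit sums of squared deviations."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.sum() / (n * k)
    ss_rows = sum(k * (values[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((values[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(PairedMeasurements(x=x, y=x.copy()))
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0
        assert "zero_variance_differences" in res.flags

    def test_constant_offset(self):
        x = np.array([5.0, 6.0, 7.0])
        res = bland_altman(PairedMeasurements(x=x, y=x + 1.0))
        assert res.bias == pytest.approx(1.0)
        assert res.loa_high - res.loa_low == pytest.approx(0.0)

    def test_worked_four_point_example(self):
        """x=(1,2,3,4), y=(1.1,2.3,3.5,4.7): differences rise 0.2 per 1.1
        of pairwise mean, so bias 0.4 and slope-on-mean 2/11."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.3, 3.5, 4.7])
        res = bland_altman(PairedMeasurements(x=x, y=y))
        assert res.bias == pytest.approx(0.4)
        assert res.prop_bias_slope == pytest.approx(0.2 / 1.1, abs=1e-12)
        # bias + mean(x) = mean(y) exactly
        assert res.bias + x.mean() == pytest.approx(y.mean(), abs=1e-12)

    def test_loa_bracket_bias(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1, 0.2, 30)
        y = x + rng.normal(0.1, 0.05, 30)
        res = bland_altman(PairedMeasurements(x=x, y=y))
        assert res.loa_low <= res.bias <= res.loa_high


class TestICC:
    def test_identical_columns_give_one(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 2))
        res = icc_consistency(m)
        assert res.icc == pytest.approx(1.0)

    def test_worked_three_by_two_matrix(self):
        """Rows (1,2),(2,4),(3,6): MSR=4.5, MSE=0.5, ICC=0.8."""
        m = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        res = icc_consistency(m)
        assert res.icc == pytest.approx(0.8, abs=1e-12)
        assert brute_force_icc_consistency(m) == pytest.approx(0.8, abs=1e-12)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for n in range(5, 11):
            for k in (2, 3):
                m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
                res = icc_consistency(m)
                assert res.icc == pytest.approx(
                    brute_force_icc_consistency(m), abs=1e-10)

    def test_matches_pingouin_two_way_mixed_consistency(self):
        """Cross-check value and CI against an independent implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        m = rng.normal(size=(12, 2)) + 2 * rng.normal(size=(12, 1))
        res = icc_consistency(m)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": m.ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        row = table[table["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin prints CI bounds rounded to 2 decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=0.0051)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=0.0051)

    def test_independent_noise_gives_icc_near_zero(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(200, 2))
        res = icc_consistency(m)
        assert abs(res.icc) < 0.15

    def test_negative_icc_reported_not_clamped(self):
        # anti-correlated columns force MSR < MSE
        m = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0], [4.0, -4.0]])
        res = icc_consistency(m)
        assert res.icc < 0 and "negative_icc" in res.flags

    def test_missing_cell_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        with pytest.raises(ValueError, match="complete-case"):
            icc_consistency(m)


class TestPairedComparison:
    def test_arithmetic(self):
        res = paired_limb_comparison([0.7, 0.8, 0.75], [1.0, 1.1, 1.05])
        assert res.mean_diff == pytest.approx(-0.3)
        assert res.mean_diff == pytest.approx(res.mean_a - res.mean_b)

    def test_identical_groups_flagged_degenerate(self):
        res = paired_limb_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert "zero_variance_differences" in res.flags
        assert np.isnan(res.t_stat)

    def test_recovers_simulated_limb_offset(self):
        """Ground truth offset −0.35 with sd 0.1, n=20: the estimate lands
        within ±0.07 (≈3 standard errors) and the test is decisive."""
        rng = np.random.default_rng(21)
        unaff = rng.normal(1.1, 0.05, 20)
        aff = unaff - 0.35 + rng.normal(0, 0.1, 20)
        res = paired_limb_comparison(aff, unaff)
        assert res.mean_diff == pytest.approx(-0.35, abs=0.07)
        assert res.p_value < 0.001
        assert res.d_paired < 0

    def test_type_one_error_calibrated(self):
        """Null paired t at α=0.05 over 2000 seeded replicates rejects
        between 3.5% and 6.5% of the time."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(2000):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            if paired_limb_comparison(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_effect_from_group_means(self):
        assert between_limb_effect(0.74, 1.11) == pytest.approx(-0.37)


class TestIqrFilter:
    def test_worked_five_point_example(self):
        """(1,2,3,4,100): Q1=2, Q3=4 under linear interpolation, upper
        fence 7, so exactly the planted outlier goes."""
        kept, removed = iqr_filter([1.0, 2.0, 3.0, 4.0, 100.0])
        assert removed == 1
        np.testing.assert_array_equal(kept, [1.0, 2.0, 3.0, 4.0])

    def test_constant_sequence_untouched(self):
        kept, removed = iqr_filter(np.full(10, 3.3))
        assert removed == 0 and len(kept) == 10

    def test_normal_sample_removal_fraction(self):
        """Tukey-fence exceedance for a normal is ~0.7%."""
        rng = np.random.default_rng(99)
        _, removed = iqr_filter(rng.normal(size=10_000))
        assert 0.004 <= removed / 10_000 <= 0.010


class TestSpearman:
    def test_perfect_negative_monotone(self):
        res = spearman_mas([5.0, 4.0, 3.0, 2.0, 1.0], [0, 1, 2, 3, 4],
                           apply_iqr=False)
        assert res.rho == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        params = rng.normal(1.0, 0.3, 30)
        mas = rng.choice([0, 1, 1.5, 2], 30)
        r1 = spearman_mas(params, mas, apply_iqr=False).rho
        r2 = spearman_mas(np.exp(params * 3), mas, apply_iqr=False).rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_equals_pearson_on_midranks(self):
        """Tied MAS values: Spearman must equal Pearson on midranks."""
        params = np.array([1.2, 1.1, 0.9, 0.8, 0.5, 0.4])
        mas = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        res = spearman_mas(params, mas, apply_iqr=False)
        oracle = stats.pearsonr(stats.rankdata(params), stats.rankdata(mas))
        assert res.rho == pytest.approx(oracle.statistic, abs=1e-12)

    def test_all_tied_mas_flagged(self):
        res = spearman_mas([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 1, 1, 1],
                           apply_iqr=False)
        assert np.isnan(res.rho) and "degenerate_constant_input" in res.flags

    def test_outlier_removed_before_correlation(self):
        params = np.array([1.2, 1.1, 0.9, 0.8, 0.5, 0.4, 50.0])
        mas = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 0.0])
        res = spearman_mas(params, mas)
        assert res.n_removed == 1 and res.n_used == 6


class TestShapiroGate:
    def test_type_one_error_near_alpha(self):
        """Normal samples n=50: the gate passes ~95% of 200 replicates."""
        rng = np.random.default_rng(55)
        passes = sum(
            shapiro_gate(rng.normal(size=50))[2] for _ in range(200))
        assert 0.92 <= passes / 200 <= 0.98

    def test_power_against_exponential(self):
        rng = np.random.default_rng(56)
        fails = sum(
            not shapiro_gate(rng.exponential(size=200))[2] for _ in range(50))
        assert fails / 50 > 0.95

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate([1.0, 2.0])

    def test_constant_input_flagged(self):
        w, p, passed = shapiro_gate(np.zeros(10))
        assert np.isnan(w) and not passed


class TestStudyReport:
    @staticmethod
    def _records(n_subjects=6, rng_seed=8):
        rng = np.random.default_rng(rng_seed)
        rows = []
        for s in range(n_subjects):
            for limb, affected in (("left", True), ("right", False)):
                base_p1 = 1.2 - 0.4 * affected + rng.normal(0, 0.05)
                mas = 2.0 if affected else 0.0
                for trial in range(1, 6):
                    true_p1 = base_p1 + rng.normal(0, 0.02)
                    for device in ("goniometer", "pose2d", "pose3d"):
                        rows.append({
                            "subject_id": f"S{s}", "limb": limb,
                            "affected": affected, "mas_flexor": mas,
                            "mas_extensor": mas, "device": device,
                            "camera_view": "none", "trial_index": trial,
                            "P1": true_p1 + rng.normal(0, 0.01),
                            "P2": 20 + rng.normal(0, 2),
                            "P3": true_p1 + rng.normal(0, 0.02),
                        })
        return pd.DataFrame(rows)

    def test_complete_cohort_populates_all_cells(self):
        tables = study_report(self._records())
        assert tables.icc_table["available"].all()
        assert tables.limb_table["available"].all()
        assert tables.correlation_table["available"].all()
        assert len(tables.icc_table) == 2 * 3 * 3   # device x stratum x param
        assert len(tables.limb_table) == 3 * 3      # device x param
        assert len(tables.correlation_table) == 3 * 2 * 3

    def test_detects_planted_structure(self):
        tables = study_report(self._records())
        p1_icc = tables.icc_table.query("parameter == 'P1'")["icc"]
        assert (p1_icc > 0.8).all()
        p1_limb = tables.limb_table.query("parameter == 'P1'")
        assert (p1_limb["effect"] < 0).all()
        rho = tables.correlation_table.query("parameter == 'P1'")["rho"]
        assert (rho < -0.5).all()

    def test_single_subject_icc_unavailable(self):
        df = self._records(n_subjects=1)
        df = df[df["trial_index"] == 1]  # one trial per limb -> 2 pairs
        tables = study_report(df)
        assert not tables.icc_table["available"].any()

    def test_row_order_invariance(self):
        df = self._records()
        t1 = study_report(df)
        t2 = study_report(df.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(
            t1.icc_table.reset_index(drop=True),
            t2.icc_table.reset_index(drop=True))
        pd.testing.assert_frame_equal(
            t1.limb_table.reset_index(drop=True),
            t2.limb_table.reset_index(drop=True))
        pd.testing.assert_frame_equal(
            t1.correlation_table.reset_index(drop=True),
            t2.correlation_table.reset_index(drop=True))

    def test_writers_emit_all_outputs(self, tmp_path):
        study_report(self._records()).write(tmp_path)
        for name in ("table1_icc.csv", "table1_icc.json", "table2_limbs.csv",
                     "table3_spearman.csv", "bland_altman_scatter.csv"):
            assert (tmp_path / name).exists()
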