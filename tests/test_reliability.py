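import math

import numpy as np
import pandas as pd
import pytest

from musclemt import (
    DegenerateDataError,
    InputError,
    bland_altman,
    icc_a1,
    mdc,
    pearson_r2,
    sem,
    sem_mdc_from_summary,
    table1_report,
)


def anova_icc_oracle(x: np.ndarray) -> float:
    """Independent ICC(A,1) via statsmodels two-way ANOVA mean squares."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = x.shape
    df = pd.DataFrame(
        {
            "value": x.ravel(),
            "target": np.repeat(np.arange(n), k).astype(str),
            "rater": np.tile(np.arange(k), n).astype(str),
        }
    )
    model = ols("value ~ C(target) + C(rater)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    msr = table.loc["C(target)", "sum_sq"] / table.loc["C(target)", "df"]
    msc = table.loc["C(rater)", "sum_sq"] / table.loc["C(rater)", "df"]
    mse = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestIccA1:
    def test_identical_columns_give_perfect_agreement(self):
        x = np.tile(np.array([1.0, 2, 3, 4, 5])[:, None], (1, 2))
        icc, lo, hi = icc_a1(x)
        assert icc == 1.0 and lo == 1.0 and hi == 1.0

    def test_fixed_table_matches_anova_oracle(self):
        x = np.array([[9.0, 2], [4.5, 4], [7.0, 6], [8.0, 5], [6.0, 3], [5.5, 7]])
        icc, _, _ = icc_a1(x)
        assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-12)

    def test_random_tables_match_anova_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 25))
            k = int(rng.integers(2, 5))
            x = rng.normal(10, 2, (n, 1)) + rng.normal(0, 1, (n, k)) + rng.normal(0, 0.5, (1, k))
            icc, _, _ = icc_a1(x)
            assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-6)

    def test_matches_established_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(50):
            n = int(rng.integers(5, 20))
            k = int(rng.integers(2, 4))
            x = rng.normal(10, 2, (n, 1)) + rng.normal(0, 1, (n, k))
            icc, lo, hi = icc_a1(x)
            df = pd.DataFrame(
                {"t": np.repeat(np.arange(n), k), "r": np.tile(np.arange(k), n), "v": x.ravel()}
            )
            row = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
            row = row[row.Type == "ICC(A,1)"].iloc[0]
            assert icc == pytest.approx(row.ICC, abs=1e-6)
            # pingouin prints its CI rounded to 2 decimals
            assert lo == pytest.approx(row.CI95[0], abs=0.006)
            assert hi == pytest.approx(row.CI95[1], abs=0.006)

    def test_pure_noise_has_near_zero_icc(self, rng):
        # no row (target) variance: expected ICC is 0
        values = [icc_a1(rng.normal(0, 1, (20, 2)))[0] for _ in range(1000)]
        assert abs(np.mean(values)) < 0.05

    def test_invariance_under_common_affine_transform(self, rng):
        x = rng.normal(10, 2, (12, 1)) + rng.normal(0, 1, (12, 3))
        icc, lo, hi = icc_a1(x)
        icc2, lo2, hi2 = icc_a1(3.0 * x + 7.0)
        assert (icc, lo, hi) == pytest.approx((icc2, lo2, hi2), abs=1e-10)

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(10, 2, (15, 1)) + rng.normal(0, 1, (15, 2))
        icc, lo, hi = icc_a1(x)
        assert lo <= icc <= hi

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            icc_a1(np.full((5, 2), 3.0))


class TestSemMdc:
    @pytest.mark.parametrize(
        "sd, icc, expected_sem",
        [(1.63, 0.953, 0.35), (1.0, 0.75, 0.5), (2.0, 1.0, 0.0)],
    )
    def test_sem_closed_form(self, sd, icc, expected_sem):
        assert round(sem(sd, icc), 2) == pytest.approx(expected_sem)

    def test_mdc_closed_form(self):
        assert mdc(0.35) == pytest.approx(0.97, abs=0.005)
        assert mdc(0.0) == 0.0
        assert mdc(1.0) == pytest.approx(2.772, abs=5e-4)

    def test_sem_rejects_icc_above_one(self):
        with pytest.raises(InputError):
            sem(1.0, 1.1)

    def test_homogeneous_in_sd(self):
        assert sem(2.0, 0.8) == pytest.approx(2 * sem(1.0, 0.8))
        assert mdc(2.0) == pytest.approx(2 * mdc(1.0))

    def test_mdc_monotone_decreasing_in_icc(self):
        values = [mdc(sem(1.5, icc)) for icc in (0.5, 0.7, 0.9, 0.99)]
        assert values == sorted(values, reverse=True)

    def test_rounded_sem_mode(self):
        s, m = sem_mdc_from_summary(1.63, 0.953, round_sem=True)
        assert s == 0.35 and round(m, 2) == 0.97


class TestBlandAltman:
    def test_identical_inputs(self):
        a = np.array([1.0, 2, 3])
        bias, sd, lo, hi = bland_altman(a, a)
        assert (bias, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([10.0, 12, 14, 16])
        bias, sd, lo, hi = bland_altman(a, a + 1.4)
        assert bias == pytest.approx(-1.4)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-1.4) and hi == pytest.approx(-1.4)

    def test_recovers_simulated_moments(self, rng):
        n = 300
        a = rng.normal(41.5, 1.7, n)
        b = a - rng.normal(1.45, 0.48, n)
        bias, sd, lo, hi = bland_altman(a, b)
        assert bias == pytest.approx(1.45, abs=3 * 0.48 / math.sqrt(n))
        assert lo < bias < hi

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            bland_altman([1.0, 2], [1.0])


class TestPearsonR2:
    def test_exact_linearity(self):
        a = np.array([1.0, 2, 3, 4])
        assert pearson_r2(a, 2 * a + 1) == pytest.approx(1.0)

    def test_sign_blind(self):
        a = np.array([1.0, 2, 3, 4])
        assert pearson_r2(a, -a) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        assert pearson_r2(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)) < 0.01

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            pearson_r2([1.0, 1, 1], [1.0, 2, 3])


class TestTable1Report:
    def make_long_df(self, rng, n_subjects=2, n_frames=30, k=2, noise=0.3):
        rows = []
        for s in range(n_subjects):
            true = rng.normal(41.5, 1.5, n_frames)
            for f in range(n_frames):
                for r in range(k):
                    rows.append(
                        {
                            "subject": f"S{s + 1}",
                            "frame": f,
                            "rater": f"m{r}",
                            "mt_mm": true[f] + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_report_has_per_subject_and_overall_rows(self, rng):
        report = table1_report(self.make_long_df(rng))
        assert list(report["subject"]) == ["S1", "S2", "Overall"]
        assert (report["icc"] > 0.8).all()
        assert np.allclose(report["sem"], report["sd"] * np.sqrt(1 - report["icc"]))
        assert np.allclose(report["mdc"], report["sem"] * 1.96 * math.sqrt(2))

    def test_degenerate_group_skipped_with_warning(self, rng):
        df = self.make_long_df(rng)
        degen = pd.DataFrame(
            {"subject": "S9", "frame": [0, 1], "rater": ["m0", "m1", "m0", "m1"][:2], "mt_mm": 5.0}
        )
        degen = pd.DataFrame(
            [
                {"subject": "S9", "frame": f, "rater": r, "mt_mm": 5.0}
                for f in range(3)
                for r in ("m0", "m1")
            ]
        )
        with pytest.warns(UserWarning, match="S9"):
            report = table1_report(pd.concat([df, degen]))
        assert "S9" not in set(report["subject"])

    def test_rounded_sem_mode_changes_mdc_input(self, rng):
        df = self.make_long_df(rng)
        full = table1_report(df, round_sem=False)
        rounded = table1_report(df, round_sem=True)
        assert np.allclose(rounded["sem"], np.round(full["sem"], 2))
        assert np.allclose(rounded["mdc"], rounded["sem"] * 1.96 * math.sqrt(2))
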