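import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eermetrics.errors import ValidationError
from eermetrics.stats import (
    anova_oneway,
    anova_twoway,
    bland_altman,
    build_report,
    icc,
    improvement_rate,
    paired_t,
    read_table,
    validate_table,
)
from eermetrics.synthetic import make_cohort


def small_table():
    rows = []
    for i, (pre, post) in enumerate([(55.0, 70.0), (60.0, 75.0), (65.0, 72.0), (50.0, 68.0)]):
        for method, d in (("ai1", 0.0), ("ai2", 0.0), ("manual", 0.5)):
            rows.append((f"P{i}", "L", "mild", method, "pre", pre + d))
            rows.append((f"P{i}", "L", "mild", method, "post", post + d))
    return pd.DataFrame(rows, columns=["patient_id", "eye", "severity", "method", "phase", "eer"])


class TestTableIO:
    def test_csv_and_xlsx_round_trip_identically(self, tmp_path):
        df = small_table()
        csv, xlsx = tmp_path / "t.csv", tmp_path / "t.xlsx"
        df.to_csv(csv, index=False)
        df.to_excel(xlsx, index=False)
        assert read_table(csv).equals(read_table(xlsx))

    def test_header_synonyms_are_mapped(self):
        df = small_table().rename(columns={"patient_id": "Patient", "eer": "EER"})
        out = validate_table(df)
        assert list(out.columns) == ["patient_id", "eye", "severity", "method", "phase", "eer"]

    def test_duplicate_keys_rejected_with_row_numbers(self):
        df = pd.concat([small_table(), small_table().iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicate"):
            validate_table(df)

    def test_non_numeric_and_out_of_range_rejected(self):
        df = small_table()
        df["eer"] = df["eer"].astype(object)
        df.loc[0, "eer"] = "abc"
        with pytest.raises(ValidationError, match="non-numeric"):
            validate_table(df)
        df = small_table()
        df.loc[0, "eer"] = 104.0
        with pytest.raises(ValidationError, match="outside"):
            validate_table(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            validate_table(small_table().drop(columns=["severity"]))


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_textbook_differences(self):
        """d = {1,2,3}: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641, df = 2."""
        t, df, p = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert df == 2

    def test_matches_scipy(self, rng):
        a = rng.normal(50, 5, 40)
        b = a + rng.normal(1, 2, 40)
        from scipy.stats import ttest_rel

        t, df, p = paired_t(a, b)
        ref = ttest_rel(b, a)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_nonzero_mean_gives_infinite_t(self):
        t, _, p = paired_t([1.0, 2.0], [3.0, 4.0])
        assert np.isinf(t) and t > 0 and p == 0.0


class TestICC:
    def test_identical_columns_give_exactly_one(self, rng):
        x = rng.normal(60, 10, 25)
        data = np.column_stack([x, x])
        for model in ("oneway_random", "twoway_random_agreement", "twoway_mixed_consistency"):
            res = icc(data, model=model)
            assert res.icc == 1.0
            assert res.interpretation == "excellent"

    def test_independent_columns_near_zero(self, rng):
        data = rng.standard_normal((10_000, 2))
        assert abs(icc(data).icc) < 0.05

    def test_invariant_under_constant_shift(self, rng):
        data = rng.normal(50, 8, (30, 3))
        res1 = icc(data)
        res2 = icc(data + 17.3)
        assert res1.icc == pytest.approx(res2.icc, abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        """Cross-check values and CIs against pingouin's implementation."""
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(60, 9, (20, 3)) + rng.normal(0, 2, (20, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "rater": np.tile(["a", "b", "c"], 20),
                "score": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        for model, typ in (
            ("oneway_random", "ICC(1,1)"),
            ("twoway_random_agreement", "ICC(A,1)"),
            ("twoway_mixed_consistency", "ICC(C,1)"),
        ):
            mine = icc(data, model=model)
            assert mine.icc == pytest.approx(ref.loc[typ, "ICC"], abs=1e-9)
            lo, hi = ref.loc[typ, "CI95"]  # pingouin rounds CIs to 2 decimals
            assert mine.ci_low == pytest.approx(lo, abs=5.1e-3)
            assert mine.ci_high == pytest.approx(hi, abs=5.1e-3)

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValidationError):
            icc(data)


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_constant_offset_collapses_limits(self):
        a = np.array([10.0, 20.0, 30.0])
        res = bland_altman(a, a + 2.5)
        assert res.bias == pytest.approx(-2.5)
        assert res.loa_low == pytest.approx(-2.5)
        assert res.loa_high == pytest.approx(-2.5)

    def test_hand_computed_limits(self):
        """d = {-1, 0, 1}: bias 0, sd 1 -> limits +-1.96."""
        res = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert res.bias == 0.0
        assert res.loa_high == pytest.approx(1.96)
        assert res.loa_low == pytest.approx(-1.96)

    def test_antisymmetric_in_argument_order(self, rng):
        a = rng.normal(60, 5, 30)
        b = rng.normal(60, 5, 30)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.bias == pytest.approx(-r2.bias)
        assert r1.loa_low == pytest.approx(-r2.loa_high)
        assert r1.loa_high == pytest.approx(-r2.loa_low)


class TestImprovementRate:
    def test_printed_mild_group_rate(self):
        assert improvement_rate(65.45, 74.87) == 14.39

    def test_pre_equals_post_is_zero(self):
        assert improvement_rate(50.0, 50.0) == 0.0

    @given(
        pre=st.floats(1.0, 99.0),
        post=st.floats(0.0, 100.0),
        c=st.floats(0.01, 50.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_scale_invariance(self, pre, post, c):
        assert improvement_rate(pre * c, post * c) == pytest.approx(
            improvement_rate(pre, post), abs=0.011
        )

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValidationError):
            improvement_rate(0.0, 10.0)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        F, dfb, dfw, p = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert F == pytest.approx(0.0)

    def test_hand_anova_table(self):
        """{1,2,3} vs {4,5,6}: SSB 13.5, MSW 1 -> F = 13.5 on (1, 4) df."""
        F, dfb, dfw, p = anova_oneway([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert F == pytest.approx(13.5)
        assert (dfb, dfw) == (1, 4)

    def test_twoway_identical_values_all_null(self):
        df = small_table()
        df["eer"] = 50.0
        df.loc[df.severity == "mild", "severity"] = np.where(
            np.arange((df.severity == "mild").sum()) % 2, "mild", "moderate_severe"
        )
        out = anova_twoway(df)
        effects = out[out.effect != "residual"]
        assert (effects["F"] == 0.0).all()
        assert (effects["p"] == 1.0).all()

    def test_twoway_detects_strong_interaction(self):
        """Moderate group improves far more than mild at n~50/group."""
        out = anova_twoway(make_cohort(seed=0))
        p_int = out.loc[out.effect == "severity:phase", "p"].item()
        assert p_int < 0.001

    def test_twoway_null_type_I_rate_calibrated(self, rng):
        """No effects simulated: interaction rejects ~5% at alpha = .05."""
        hits = 0
        reps = 300
        for rep in range(reps):
            n = 10
            df = pd.DataFrame(
                {
                    "patient_id": [f"P{i}" for i in range(4 * n)],
                    "eye": "L",
                    "severity": ["mild"] * 2 * n + ["moderate_severe"] * 2 * n,
                    "method": "ai1",
                    "phase": (["pre"] * n + ["post"] * n) * 2,
                    "eer": rng.normal(60, 5, 4 * n).clip(0, 100),
                }
            )
            out = anova_twoway(df)
            if out.loc[out.effect == "severity:phase", "p"].item() < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 0.045  # 3+ MC standard errors


class TestBuildReport:
    def test_zero_jitter_cohort_gives_perfect_agreement(self):
        table = make_cohort(manual_jitter_sd=0.0, seed=3)
        report = build_report(table)
        for key, entry in report.iccs.items():
            assert entry["icc"] == 1.0
        for ba in report.bland_altman.values():
            assert ba.bias == pytest.approx(0.0, abs=1e-12)

    def test_jittered_manual_limits_match_closed_form(self):
        """manual = ai1 + N(0, 1.8) -> LoA half-width ~ 1.96 * 1.8 = 3.53."""
        table = make_cohort({"mild": 50, "moderate_severe": 50}, manual_jitter_sd=1.8, seed=11)
        report = build_report(table)
        ba = report.bland_altman["ai1_vs_manual"]
        half_width = (ba.loa_high - ba.loa_low) / 2
        assert half_width == pytest.approx(1.96 * 1.8, abs=0.8)

    def test_severity_rows_and_improvement_rates_present(self):
        report = build_report(make_cohort(seed=4))
        groups = set(report.severity_summary["group"])
        assert {"all", "mild", "moderate_severe"} <= groups
        assert report.phase_summary["p"].max() < 0.001  # surgery effect is large

    def test_report_serializes_to_plain_types(self):
        import json

        report = build_report(make_cohort(seed=4))
        json.dumps(report.to_dict(), default=float)

    def test_deposited_style_workbook_reproduction_machinery(self, tmp_path):
        """reproduce_s1_checks on a synthetic stand-in workbook."""
        from eermetrics.stats import reproduce_s1_checks

        path = tmp_path / "synthetic_s1.xlsx"
        make_cohort(manual_jitter_sd=1.0, seed=6).to_excel(path, index=False)
        out = reproduce_s1_checks(path)
        methods = {row["method"] for row in out["phase_summary"]}
        assert {"ai1", "ai2", "manual"} <= methods
        assert out["icc"]["ai1_vs_ai2_pre"]["icc"] == 1.0
        assert "ai1_vs_manual" in out["bland_altman"]
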