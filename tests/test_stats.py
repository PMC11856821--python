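"""Cohort statistics: test selection, correlation panels, audits."""

import numpy as np
import pandas as pd
import pytest

from sizedose import (
    InsufficientDataError,
    compare_groups,
    correlation_panel,
    deff_census,
    scan_length_audit,
    size_specific_comparison,
    spearman,
    summarize,
)

from conftest import make_cohort_df


class TestCompareGroups:
    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, 100)
        comp = compare_groups(x, x.copy())
        assert comp.p_value > 0.9
        assert comp.mean_a == comp.mean_b

    def test_normal_shifted_samples_use_student_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(0.5, 1.0, 200)
        comp = compare_groups(a, b)
        assert comp.test_used == "student_t"
        assert comp.p_value < 0.05

    def test_heavy_tailed_sample_triggers_mann_whitney(self):
        rng = np.random.default_rng(2)
        a = rng.standard_cauchy(200)
        b = rng.normal(0.0, 1.0, 200)
        comp = compare_groups(a, b)
        assert comp.test_used == "mann_whitney_u"

    def test_symmetric_under_group_exchange(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.4, 1, 60)
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-9)
        assert ab.statistic == pytest.approx(-ba.statistic, rel=1e-9)
        # also for the rank-based branch
        ab = compare_groups(np.exp(a), np.exp(b) ** 3)
        ba = compare_groups(np.exp(b) ** 3, np.exp(a))
        assert ab.test_used == "mann_whitney_u"
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-9)
        assert ab.statistic == pytest.approx(-ba.statistic, rel=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        y = x + rng.normal(scale=0.5, size=80)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_perfect_monotone_relations(self):
        x = np.arange(20.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_variable_flagged_nan(self):
        rho, p = spearman(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_small_n_uses_permutation_p(self):
        # strongly associated tiny sample: permutation p must be small but
        # bounded below by 1/(n_resamples+1), never the asymptotic value
        x = np.arange(8.0)
        y = x + 0.01 * np.sin(x)
        rho, p = spearman(x, y)
        assert rho == pytest.approx(1.0)
        assert 0 < p < 0.05


def test_correlation_panel_stratified(default_synthetic):
    from sizedose import combined_frame, metrics_frame

    df = combined_frame(default_synthetic, metrics_frame(default_synthetic.df))
    panel = correlation_panel(df)
    assert set(panel["stratum"]) == {"female", "male"}
    deff_rows = panel[panel["variable"] == "deff_mm"]
    assert (deff_rows["rho"] > 0.7).all()  # dose tracks size under modulation
    assert ((panel["rho"].dropna() >= -1) & (panel["rho"].dropna() <= 1)).all()


class TestScanLengthAudit:
    def test_all_equal_lengths(self):
        df = make_cohort_df([{"topogram_length_mm": 480.0, "scan_length_mm": 480.0}] * 5)
        audit = scan_length_audit(df, by=None)
        assert audit.pct_unchanged == 100.0
        assert audit.pct_reduced == audit.pct_increased == 0.0
        assert audit.mean_change_mm == 0.0

    def test_fractions_sum_to_100(self, default_synthetic):
        audit = scan_length_audit(default_synthetic.df)
        total = audit.pct_reduced + audit.pct_increased + audit.pct_unchanged
        assert total == pytest.approx(100.0, abs=0.1)
        for sub in audit.per_sex.values():
            assert sub["pct_reduced"] + sub["pct_increased"] + sub["pct_unchanged"] == (
                pytest.approx(100.0, abs=0.1)
            )

    def test_mean_change_is_diagnostic_minus_topogram(self):
        df = make_cohort_df(
            [
                {"topogram_length_mm": 485.73, "scan_length_mm": 474.28},
                {"topogram_length_mm": 476.98, "scan_length_mm": 457.45},
            ]
        )
        audit = scan_length_audit(df, by=None)
        assert audit.mean_change_mm == pytest.approx((-11.45 - 19.53) / 2, abs=1e-9)
        single = scan_length_audit(df.iloc[[0]], by=None)
        assert single.mean_change_mm == pytest.approx(-11.45)


class TestDeffCensus:
    def test_all_below(self):
        census = deff_census([319.0] * 10)
        assert census.pct_below_reference == 100.0
        assert census.pct_at_or_above_reference == 0.0

    def test_tie_counts_as_not_smaller(self):
        census = deff_census([320.0, 300.0])
        assert census.pct_below_reference == 50.0
        assert census.pct_at_or_above_reference == 50.0

    def test_deviation_reported_both_ways(self):
        census = deff_census([290.44], reference_mm=320.0)
        assert census.deviation_of_mean_pct == pytest.approx(9.2375, abs=1e-3)
        assert census.mean_abs_deviation_pct == pytest.approx(9.2375, abs=1e-3)

    def test_fractions_sum(self, default_synthetic):
        deff = np.sqrt(default_synthetic.df["ap_mm"] * default_synthetic.df["lat_mm"])
        census = deff_census(deff)
        assert census.pct_below_reference + census.pct_at_or_above_reference == (
            pytest.approx(100.0)
        )


class TestSummarize:
    def test_equal_values_sd_zero(self):
        df = pd.DataFrame({"x": [3.0, 3.0], "sex": ["female", "female"]})
        summary = summarize(df, variables=["x"], by=None)
        assert summary.by_stratum["all"].loc["x", "sd"] == 0.0

    def test_single_record_stratum_sd_unavailable(self):
        df = pd.DataFrame({"x": [3.0, 4.0, 5.0, 9.0], "sex": ["female"] * 3 + ["male"]})
        summary = summarize(df, variables=["x"])
        assert np.isnan(summary.by_stratum["male"].loc["x", "sd"])
        assert summary.by_stratum["male"].loc["x", "mean"] == 9.0
        assert not summary.comparisons  # male stratum below minimum n

    def test_moment_recovery_synthetic(self):
        """At n = 5000 the generator reproduces its per-sex targets within 2 SE."""
        from dataclasses import replace

        from sizedose import SimulationConfig, generate

        cfg = replace(SimulationConfig(), n=5000)
        df = generate(cfg, seed=11).df
        summary = summarize(df, variables=["height_cm", "weight_kg"])
        for sex, params in (("female", cfg.female), ("male", cfg.male)):
            tab = summary.by_stratum[sex]
            n = tab.loc["height_cm", "n"]
            # BMI truncation trims the marginals slightly; 2 SE plus a
            # small truncation allowance
            for var, mean, sd in (
                ("height_cm", params.height_mean, params.height_sd),
                ("weight_kg", params.weight_mean, params.weight_sd),
            ):
                se = sd / np.sqrt(n)
                assert abs(tab.loc[var, "mean"] - mean) < 2 * se + 0.02 * mean


class TestSizeSpecificComparison:
    def test_unit_k_means_no_increase(self):
        metrics = pd.DataFrame(
            {
                "region": ["abdomen_pelvis"] * 4,
                "sex": ["female", "male"] * 2,
                "dlp_mGycm": [400.0, 500.0, 450.0, 520.0],
                "dlp_ss_mGycm": [400.0, 500.0, 450.0, 520.0],
                "ed_mSv": [6.0, 7.5, 6.75, 7.8],
                "ed_ss_mSv": [6.0, 7.5, 6.75, 7.8],
            }
        )
        out = size_specific_comparison(metrics)
        assert (out["ed_pct_increase"].abs() < 1e-12).all()
        assert (out["dlp_pct_increase"].abs() < 1e-12).all()

    def test_printed_mean_pairs(self):
        """Percent increases computed from the audit's published means."""
        metrics = pd.DataFrame(
            {
                "region": ["abdomen_pelvis", "chest"],
                "sex": ["female", "male"],
                "dlp_mGycm": [514.88, 314.98],
                "dlp_ss_mGycm": [627.83, 364.89],
                "ed_mSv": [7.72, 4.41],
                "ed_ss_mSv": [9.42, 5.11],
            }
        )
        out = size_specific_comparison(metrics).set_index("region")
        abd = out.loc["abdominal" if "abdominal" in out.index else "abdomen_pelvis"]
        abd = abd[abd["stratum"] == "all"].iloc[0] if isinstance(abd, pd.DataFrame) else abd
        assert round(abd["ed_pct_increase"]) == 22
        assert abd["dlp_pct_increase"] == pytest.approx(21.94, abs=0.01)
        chest = out.loc["chest"]
        chest = (
            chest[chest["stratum"] == "all"].iloc[0]
            if isinstance(chest, pd.DataFrame)
            else chest
        )
        assert round(chest["ed_pct_increase"]) == 16

    def test_absent_region_skipped(self):
        metrics = pd.DataFrame(
            {
                "region": ["abdomen_pelvis"] * 3,
                "sex": ["female"] * 3,
                "dlp_mGycm": [400.0, 500.0, 450.0],
                "dlp_ss_mGycm": [480.0, 610.0, 560.0],
                "ed_mSv": [6.0, 7.5, 6.75],
                "ed_ss_mSv": [7.2, 9.15, 8.4],
            }
        )
        out = size_specific_comparison(metrics, regions=["abdomen_pelvis", "chest"])
        assert set(out["region"]) == {"abdomen_pelvis"}

    def test_dlpss_mean_bracketed_by_k_range(self, default_synthetic):
        from sizedose import metrics_frame

        m = metrics_frame(default_synthetic.df)
        mean_dlp = default_synthetic.df["dlp_mGycm"].mean()
        assert mean_dlp * m["k"].min() <= m["dlp_ss_mGycm"].mean() <= mean_dlp * m["k"].max()
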