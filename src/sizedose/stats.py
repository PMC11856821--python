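"""Cohort-level statistics for the dose audit.

The protocol mirrors common radiology-audit practice: Shapiro-Wilk
normality screening per variable per group; Student's t (Welch form)
when both groups look normal, Mann-Whitney U otherwise; Spearman rank
correlations throughout (most dose variables are right-skewed); alpha =
0.05, two-sided, no multiple-testing correction (each test is reported
at its nominal level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .metrics import percent_increase

ALPHA = 0.05

#: Variables summarised in the standard audit tables, by metrics-CSV column.
DEFAULT_SUMMARY_VARIABLES = [
    "age_years",
    "weight_kg",
    "height_cm",
    "bmi",
    "lat_mm",
    "ap_mm",
    "deff_mm",
    "topogram_length_mm",
    "scan_length_mm",
    "scan_length_change_mm",
    "ctdi_vol_mGy",
    "ssde_mGy",
    "dlp_mGycm",
    "dlp_ss_mGycm",
    "ed_mSv",
    "ed_ss_mSv",
]

#: Anthropometric correlates examined against CTDIvol.
DEFAULT_CORRELATES = [
    "age_years",
    "weight_kg",
    "height_cm",
    "bmi",
    "lat_mm",
    "ap_mm",
    "deff_mm",
    "scan_length_mm",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group location comparison with a normality-gated test choice.

    ``statistic`` flips sign under group exchange: the t statistic for
    Student's test, the centred Mann-Whitney statistic U - n1*n2/2
    otherwise. ``normality_p`` holds the per-group Shapiro-Wilk p-values.
    """

    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test_used: str  # "student_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]


@dataclass
class CohortSummary:
    """Sex-stratified descriptive tables plus between-sex comparisons.

    ``by_stratum`` maps stratum label (plus ``"all"``) to a DataFrame
    indexed by variable with columns n/mean/sd/min/max; ``comparisons``
    maps variable to its :class:`GroupComparison` (absent when a stratum
    is empty or too small). Single-record strata get mean only, sd NaN.
    """

    by_stratum: dict[str, pd.DataFrame]
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    missing_strata: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ScanLengthAudit:
    """Diagnostic-vs-topogram scan-range discipline."""

    pct_reduced: float
    pct_increased: float
    pct_unchanged: float
    mean_change_mm: float
    sd_change_mm: float
    mean_change_pct: float
    per_sex: dict[str, dict[str, float]]
    sex_comparison: GroupComparison | None


@dataclass(frozen=True)
class DeffCensus:
    """Share of patients smaller/larger than the reference phantom.

    Two deviation summaries are reported because the averaging base is
    ambiguous: ``deviation_of_mean_pct`` = (ref - mean Deff)/ref and
    ``mean_abs_deviation_pct`` = mean(|Deff - ref|)/ref, both in %.
    """

    pct_below_reference: float
    pct_at_or_above_reference: float
    reference_mm: float
    deviation_of_mean_pct: float
    mean_abs_deviation_pct: float


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = ALPHA,
    variable: str = "",
) -> GroupComparison:
    """Normality-gated two-sided comparison of two independent samples.

    Shapiro-Wilk is run on each group; Welch's t-test is used iff both
    p >= alpha, otherwise the Mann-Whitney U test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"compare_groups needs >= 3 observations per group, got {len(a)} and {len(b)}"
        )

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:  # constant sample: trivially non-normal
            return 0.0
        return float(sps.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa >= alpha and pb >= alpha:
        res = sps.ttest_ind(a, b, equal_var=False)
        test, stat, p = "student_t", float(res.statistic), float(res.pvalue)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        # centre U so the statistic is antisymmetric under group exchange
        test, stat, p = "mann_whitney_u", float(res.statistic) - len(a) * len(b) / 2.0, float(
            res.pvalue
        )
    return GroupComparison(
        variable=variable,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        n_a=len(a),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        n_b=len(b),
        test_used=test,
        statistic=stat,
        p_value=p,
        normality_p=(pa, pb),
    )


def _describe(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=list(variables), columns=["n", "mean", "sd", "min", "max"],
                       dtype=float)
    for var in variables:
        x = df[var].to_numpy(float)
        out.loc[var, "n"] = len(x)
        if len(x):
            out.loc[var, ["mean", "min", "max"]] = [np.mean(x), np.min(x), np.max(x)]
            out.loc[var, "sd"] = np.std(x, ddof=1) if len(x) > 1 else np.nan
    return out


def summarize(
    df: pd.DataFrame,
    variables: Sequence[str] | None = None,
    by: str | None = "sex",
) -> CohortSummary:
    """Mean/SD/min/max per variable, overall and per stratum, with
    between-stratum p-values when exactly two strata are present."""
    variables = [v for v in (variables or DEFAULT_SUMMARY_VARIABLES) if v in df.columns]
    tables = {"all": _describe(df, variables)}
    comparisons: dict[str, GroupComparison] = {}
    missing: list[str] = []
    if by is not None and by in df.columns:
        groups = {str(lvl): sub for lvl, sub in df.groupby(by)}
        for lvl, sub in groups.items():
            if sub.empty:
                missing.append(lvl)
                continue
            tables[lvl] = _describe(sub, variables)
        if len(groups) == 2:
            (la, ga), (lb, gb) = sorted(groups.items())
            for var in variables:
                if len(ga) >= 3 and len(gb) >= 3:
                    comparisons[var] = compare_groups(ga[var], gb[var], variable=var)
    return CohortSummary(by_stratum=tables, comparisons=comparisons, missing_strata=missing)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_below_n: int = 30,
    random_state: int = 0,
) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    Uses the large-sample t approximation; below ``exact_below_n``
    observations the p-value comes from a seeded pairing-permutation
    test instead (the asymptotic p is unreliable at small n).
    Returns (nan, nan) when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("spearman needs >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    if len(x) < exact_below_n:
        perm = sps.permutation_test(
            (x, y),
            lambda a, b: sps.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            alternative="two-sided",
            rng=np.random.default_rng(random_state),
        )
        p = perm.pvalue
    return float(rho), float(p)


def correlation_panel(
    df: pd.DataFrame,
    x_vars: Sequence[str] | None = None,
    y_var: str = "ctdi_vol_mGy",
    by: str | None = "sex",
) -> pd.DataFrame:
    """Spearman correlations of ``y_var`` against each of ``x_vars``,
    per stratum. Constant variables are flagged with rho = NaN."""
    x_vars = [v for v in (x_vars or DEFAULT_CORRELATES) if v in df.columns]
    strata: Mapping[str, pd.DataFrame]
    if by is not None and by in df.columns:
        strata = {str(lvl): sub for lvl, sub in df.groupby(by)}
    else:
        strata = {"all": df}
    rows = []
    for stratum, sub in strata.items():
        for var in x_vars:
            pair = sub[[var, y_var]].dropna()
            if len(pair) < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman(pair[var], pair[y_var])
            rows.append(
                {
                    "stratum": stratum,
                    "variable": var,
                    "rho": rho,
                    "p_value": p,
                    "n": len(pair),
                    "flag": "constant" if np.isnan(rho) and len(pair) >= 3 else "",
                }
            )
    return pd.DataFrame(rows)


def scan_length_audit(df: pd.DataFrame, by: str | None = "sex") -> ScanLengthAudit:
    """Three-bin audit of diagnostic-vs-topogram scan length.

    Change = diagnostic - topogram per record; fractions of reduced
    (< 0), increased (> 0) and unchanged (= 0) scans; mean +/- SD change
    in mm and in % of the topogram length; per-sex breakdown and a
    between-sex comparison of the changes.
    """
    change = df["scan_length_mm"].to_numpy(float) - df["topogram_length_mm"].to_numpy(float)
    pct = 100.0 * change / df["topogram_length_mm"].to_numpy(float)
    n = len(change)

    def _stats(c: np.ndarray, p: np.ndarray) -> dict[str, float]:
        return {
            "pct_reduced": 100.0 * np.mean(c < 0) if len(c) else float("nan"),
            "pct_increased": 100.0 * np.mean(c > 0) if len(c) else float("nan"),
            "pct_unchanged": 100.0 * np.mean(c == 0) if len(c) else float("nan"),
            "mean_change_mm": float(np.mean(c)) if len(c) else float("nan"),
            "sd_change_mm": float(np.std(c, ddof=1)) if len(c) > 1 else float("nan"),
            "mean_change_pct": float(np.mean(p)) if len(c) else float("nan"),
            "n": len(c),
        }

    per_sex: dict[str, dict[str, float]] = {}
    comparison = None
    if by is not None and by in df.columns:
        groups = {str(lvl): np.flatnonzero((df[by] == lvl).to_numpy()) for lvl in df[by].unique()}
        for lvl, idx in sorted(groups.items()):
            per_sex[lvl] = _stats(change[idx], pct[idx])
        if len(groups) == 2 and all(len(i) >= 3 for i in groups.values()):
            (la, ia), (lb, ib) = sorted(groups.items())
            comparison = compare_groups(change[ia], change[ib], variable="scan_length_change_mm")
    overall = _stats(change, pct)
    return ScanLengthAudit(
        pct_reduced=overall["pct_reduced"],
        pct_increased=overall["pct_increased"],
        pct_unchanged=overall["pct_unchanged"],
        mean_change_mm=overall["mean_change_mm"],
        sd_change_mm=overall["sd_change_mm"],
        mean_change_pct=overall["mean_change_pct"],
        per_sex=per_sex,
        sex_comparison=comparison,
    )


def deff_census(deff_mm: Sequence[float], reference_mm: float = 320.0) -> DeffCensus:
    """Fractions of effective diameters below vs at-or-above the
    reference phantom diameter. A Deff exactly at the reference counts
    as "not smaller" (the at-or-above bin)."""
    d = np.asarray(deff_mm, dtype=float)
    if len(d) == 0:
        raise InsufficientDataError("deff_census needs at least one record")
    below = 100.0 * np.mean(d < reference_mm)
    return DeffCensus(
        pct_below_reference=float(below),
        pct_at_or_above_reference=float(100.0 - below),
        reference_mm=reference_mm,
        deviation_of_mean_pct=float(100.0 * (reference_mm - np.mean(d)) / reference_mm),
        mean_abs_deviation_pct=float(100.0 * np.mean(np.abs(d - reference_mm)) / reference_mm),
    )


def size_specific_comparison(
    metrics: pd.DataFrame,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Traditional vs size-specific dose indices per region and stratum.

    One row per (region, stratum): mean DLP vs DLPss and ED vs EDss with
    their percent increases, plus the between-sex p-value for the
    size-specific quantities where both sexes are present. Regions with
    no records are skipped.
    """
    regions = regions or sorted(metrics["region"].unique())
    rows = []
    for region in regions:
        sub = metrics[metrics["region"] == region]
        if sub.empty:
            continue
        strata: list[tuple[str, pd.DataFrame]] = [("all", sub)]
        strata += [(str(lvl), g) for lvl, g in sub.groupby("sex")]
        sexes = {str(lvl): g for lvl, g in sub.groupby("sex")}
        p_ed_ss = p_dlp_ss = float("nan")
        if len(sexes) == 2 and all(len(g) >= 3 for g in sexes.values()):
            (_, ga), (_, gb) = sorted(sexes.items())
            p_dlp_ss = compare_groups(ga["dlp_ss_mGycm"], gb["dlp_ss_mGycm"]).p_value
            p_ed_ss = compare_groups(ga["ed_ss_mSv"], gb["ed_ss_mSv"]).p_value
        for label, g in strata:
            mean_dlp = float(g["dlp_mGycm"].mean()) if "dlp_mGycm" in g else float("nan")
            mean_dlpss = float(g["dlp_ss_mGycm"].mean())
            mean_ed = float(g["ed_mSv"].mean())
            mean_edss = float(g["ed_ss_mSv"].mean())
            rows.append(
                {
                    "region": region,
                    "stratum": label,
                    "n": len(g),
                    "mean_dlp_mGycm": mean_dlp,
                    "mean_dlp_ss_mGycm": mean_dlpss,
                    "dlp_pct_increase": percent_increase(mean_dlpss, mean_dlp)
                    if mean_dlp == mean_dlp
                    else float("nan"),
                    "mean_ed_mSv": mean_ed,
                    "mean_ed_ss_mSv": mean_edss,
                    "ed_pct_increase": percent_increase(mean_edss, mean_ed),
                    "p_sex_dlp_ss": p_dlp_ss,
                    "p_sex_ed_ss": p_ed_ss,
                }
            )
    return pd.DataFrame(rows)
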