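"""Render audit tables (CSV or Markdown) and the standard figures."""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .stats import (
    CohortSummary,
    DeffCensus,
    ScanLengthAudit,
)


def _round_frame(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


def to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style Markdown table (no external dependency)."""
    df = df.reset_index() if df.index.name or not df.index.equals(pd.RangeIndex(len(df))) else df
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for row in df.itertuples(index=False):
        lines.append("| " + " | ".join("" if v is None else str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: Path, fmt: str = "csv", decimals: int = 2) -> Path:
    df = _round_frame(df, decimals)
    if fmt == "md":
        path = path.with_suffix(".md")
        path.write_text(to_markdown(df))
    else:
        path = path.with_suffix(".csv")
        df.to_csv(path, index=False)
    return path


def summary_frames(summary: CohortSummary) -> dict[str, pd.DataFrame]:
    """Flatten a CohortSummary into mean/female/male/p style tables."""
    frames: dict[str, pd.DataFrame] = {}
    for stratum, table in summary.by_stratum.items():
        frames[stratum] = table.reset_index(names="variable")
    if summary.comparisons:
        rows = []
        for var, comp in summary.comparisons.items():
            rows.append(
                {
                    "variable": var,
                    "mean_all": summary.by_stratum["all"].loc[var, "mean"],
                    "sd_all": summary.by_stratum["all"].loc[var, "sd"],
                    f"mean_{'female'}": comp.mean_a,
                    f"sd_{'female'}": comp.sd_a,
                    f"mean_{'male'}": comp.mean_b,
                    f"sd_{'male'}": comp.sd_b,
                    "test": comp.test_used,
                    "p_value": comp.p_value,
                }
            )
        frames["comparison"] = pd.DataFrame(rows)
    return frames


def audit_frame(audit: ScanLengthAudit) -> pd.DataFrame:
    rows = [
        {
            "stratum": "all",
            "pct_reduced": audit.pct_reduced,
            "pct_increased": audit.pct_increased,
            "pct_unchanged": audit.pct_unchanged,
            "mean_change_mm": audit.mean_change_mm,
            "sd_change_mm": audit.sd_change_mm,
            "mean_change_pct": audit.mean_change_pct,
        }
    ]
    for sex, s in audit.per_sex.items():
        rows.append({"stratum": sex, **{k: v for k, v in s.items() if k != "n"}})
    df = pd.DataFrame(rows)
    if audit.sex_comparison is not None:
        df["p_sex"] = audit.sex_comparison.p_value
    return df


def census_frame(census: DeffCensus) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_mm": census.reference_mm,
                "pct_below_reference": census.pct_below_reference,
                "pct_at_or_above_reference": census.pct_at_or_above_reference,
                "deviation_of_mean_pct": census.deviation_of_mean_pct,
                "mean_abs_deviation_pct": census.mean_abs_deviation_pct,
            }
        ]
    )


def scatter_figure(
    x: Any, y: Any, rho: float, xlabel: str, ylabel: str, path: Path
) -> Path:
    """Scatter plot with the Spearman rho annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.asarray(x), np.asarray(y), s=8, alpha=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.annotate(f"Spearman rho = {rho:.2f}", xy=(0.05, 0.92), xycoords="axes fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def census_figure(census: DeffCensus, path: Path) -> Path:
    """Bar chart of the below/at-or-above reference split."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(
        [f"< {census.reference_mm:.0f} mm", f">= {census.reference_mm:.0f} mm"],
        [census.pct_below_reference, census.pct_at_or_above_reference],
        color=["tab:blue", "tab:orange"],
    )
    ax.set_ylabel("% of examinations")
    ax.set_title("Effective diameter vs reference phantom")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
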