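"""Cohort file handling: read, validate, filter and write the CSV schema.

Schema (version 1), comma-separated, UTF-8, dot decimal, header required::

    exam_id, sex, age_years, weight_kg, height_cm, ap_mm, lat_mm,
    topogram_length_mm, scan_length_mm, ctdi_vol_mGy, dlp_mGycm,
    region, phantom, exclusion_flags

``exclusion_flags`` is a semicolon-separated list of free-text codes
(e.g. ``ascites;motion_artifact``) standing in for exclusion criteria
that require image review; an empty cell means no flags. Malformed rows
are never silently dropped: they are collected as :class:`RowError`
entries with their 1-based data row number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import SchemaError
from .metrics import compute_bmi
from .records import ExamRecord, PHANTOMS, REGIONS, SEXES

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

COHORT_COLUMNS: list[str] = [
    "exam_id",
    "sex",
    "age_years",
    "weight_kg",
    "height_cm",
    "ap_mm",
    "lat_mm",
    "topogram_length_mm",
    "scan_length_mm",
    "ctdi_vol_mGy",
    "dlp_mGycm",
    "region",
    "phantom",
    "exclusion_flags",
]

METRIC_COLUMNS: list[str] = [
    "bmi",
    "deff_mm",
    "k",
    "ssde_mGy",
    "ed_mSv",
    "dlp_ss_mGycm",
    "ed_ss_mSv",
    "ctdi_bias",
    "scan_length_change_mm",
]

_NUMERIC = [
    "age_years",
    "weight_kg",
    "height_cm",
    "ap_mm",
    "lat_mm",
    "topogram_length_mm",
    "scan_length_mm",
    "ctdi_vol_mGy",
    "dlp_mGycm",
]
_POSITIVE = _NUMERIC[1:]  # everything but age must be strictly positive


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data row number (header not counted)
    exam_id: str
    field: str
    message: str


@dataclass(frozen=True)
class InclusionPolicy:
    """Which examinations enter the analysis.

    Adults with BMI inside the closed interval [bmi_min, bmi_max] and no
    exclusion flags are retained.
    """

    bmi_min: float = 18.0
    bmi_max: float = 35.0
    adult_min_age: float = 18.0

    def __post_init__(self) -> None:
        if not self.bmi_min < self.bmi_max:
            raise ValueError("bmi_min must be < bmi_max")


@dataclass
class CohortTable:
    """Validated cohort rows plus row-level error reports.

    ``df`` holds one row per valid examination in schema order; after
    :func:`apply_inclusion` it additionally carries ``included`` and
    ``exclusion_reasons`` columns. ``errors`` lists rows that failed
    validation on read.
    """

    df: pd.DataFrame
    errors: list[RowError] = field(default_factory=list)
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def retained(self) -> pd.DataFrame:
        if "included" in self.df.columns:
            return self.df[self.df["included"]]
        return self.df

    def records(self) -> Iterator[ExamRecord]:
        for row in self.retained.itertuples(index=False):
            yield ExamRecord(
                exam_id=row.exam_id,
                sex=row.sex,
                age=row.age_years,
                weight=row.weight_kg,
                height=row.height_cm,
                ap=row.ap_mm,
                lat=row.lat_mm,
                topogram_length=row.topogram_length_mm,
                scan_length=row.scan_length_mm,
                ctdi_vol=row.ctdi_vol_mGy,
                dlp=row.dlp_mGycm,
                region=row.region,
                phantom=row.phantom,
            )


def _validate_rows(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    bad = np.zeros(len(raw), dtype=bool)

    def flag(mask: np.ndarray, fieldname: str, message: str) -> None:
        for i in np.flatnonzero(mask & ~bad):
            errors.append(
                RowError(row=i + 1, exam_id=str(raw["exam_id"].iat[i]), field=fieldname,
                         message=message)
            )
        bad[mask] = True

    parsed = raw.copy()
    for col in _NUMERIC:
        values = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        flag(values.isna().to_numpy(), col, "not a number")
        parsed[col] = values
    for col in _POSITIVE:
        with np.errstate(invalid="ignore"):
            flag((parsed[col] <= 0).to_numpy(), col, "must be > 0")
    flag((parsed["age_years"] < 0).to_numpy(), "age_years", "must be >= 0")
    flag(~raw["sex"].isin(SEXES).to_numpy(), "sex", f"must be one of {SEXES}")
    flag(~raw["region"].isin(REGIONS).to_numpy(), "region", f"must be one of {REGIONS}")
    flag(~raw["phantom"].isin(PHANTOMS).to_numpy(), "phantom", f"must be one of {PHANTOMS}")
    flag(
        (raw["region"].isin(("abdomen_pelvis", "chest")) & (raw["phantom"] != "body32")).to_numpy(),
        "phantom",
        "trunk regions require the body32 phantom",
    )
    flag(raw["exam_id"].duplicated(keep="first").to_numpy(), "exam_id", "duplicate exam_id")

    good = parsed[~bad].reset_index(drop=True)
    return good, errors


def read_cohort(path: str | Path, schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` if required columns are missing; rows
    failing validation are reported in ``CohortTable.errors``.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing required columns: {missing}")
    raw = raw[COHORT_COLUMNS]
    df, errors = _validate_rows(raw)
    if errors:
        logger.warning("%d malformed row(s) in %s", len(errors), path)
    return CohortTable(df=df, errors=errors)


def apply_inclusion(table: CohortTable, policy: InclusionPolicy | None = None) -> CohortTable:
    """Apply the inclusion policy, annotating rather than dropping rows.

    Per-reason exclusion counts land in ``exclusion_counts``; a record
    excluded for several reasons increments each reason once. Idempotent.
    """
    policy = policy or InclusionPolicy()
    df = table.df.copy()
    bmi = np.array(
        [compute_bmi(w, h) for w, h in zip(df["weight_kg"], df["height_cm"])]
    ) if len(df) else np.array([])
    reasons: list[list[str]] = [[] for _ in range(len(df))]
    for i in range(len(df)):
        if bmi[i] < policy.bmi_min:
            reasons[i].append("bmi_below_min")
        elif bmi[i] > policy.bmi_max:
            reasons[i].append("bmi_above_max")
        if df["age_years"].iat[i] < policy.adult_min_age:
            reasons[i].append("underage")
        flags = str(df["exclusion_flags"].iat[i]).strip()
        if flags and flags.lower() != "nan":
            for code in flags.split(";"):
                code = code.strip()
                if code:
                    reasons[i].append(f"flag:{code}")
    df["included"] = [not r for r in reasons]
    df["exclusion_reasons"] = [";".join(r) for r in reasons]
    counts: dict[str, int] = {}
    for r in reasons:
        for code in r:
            counts[code] = counts.get(code, 0) + 1
    if not df["included"].any():
        logger.warning("inclusion policy retained no records")
    return CohortTable(df=df, errors=list(table.errors), exclusion_counts=counts)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort back to CSV in schema column order."""
    table.df[COHORT_COLUMNS].to_csv(path, index=False)


def combined_frame(table: CohortTable, metrics: pd.DataFrame) -> pd.DataFrame:
    """Retained schema columns side by side with the derived metric columns."""
    base = table.retained[COHORT_COLUMNS].reset_index(drop=True)
    derived = metrics.reset_index(drop=True)[METRIC_COLUMNS]
    if len(base) != len(derived):
        raise SchemaError(
            f"metrics rows ({len(derived)}) do not match retained records ({len(base)})"
        )
    return pd.concat([base, derived], axis=1)


def write_metrics(table: CohortTable, metrics: pd.DataFrame, path: str | Path) -> None:
    """Write one row per retained record: the 14 schema columns followed
    by the 9 derived metric columns, full precision."""
    combined_frame(table, metrics).to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV produced by :func:`write_metrics`."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS + METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metrics file {path} missing columns: {missing}")
    return df
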