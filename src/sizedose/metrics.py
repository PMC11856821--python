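"""Per-examination dose formulas.

The chain of quantities, all elementary products:

    BMI   = weight / height_m^2                 [kg/m^2]
    Deff  = sqrt(AP * LAT)                      [mm]  geometric mean
    SSDE  = CTDIvol * k(Deff)                   [mGy] size-specific dose estimate
    ED    = DLP * f(region)                     [mSv] effective dose
    DLPss = DLP * k(Deff)                       [mGy*cm] size-specific DLP
    EDss  = DLPss * f(region)                   [mSv] size-specific effective dose

where k is the phantom-specific conversion factor (see
:mod:`sizedose.conversion`) and f the region-specific DLP-to-ED
coefficient in mSv/(mGy*cm). By construction
EDss/ED = DLPss/DLP = SSDE/CTDIvol = k for every record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conversion import ConversionModel
from .errors import ConfigurationError, SizedoseError, ValidationError
from .records import DoseMetrics, ExamRecord

# Region -> f coefficient, mSv per mGy*cm. Abdomen/pelvis 0.015; chest 0.014
# (the conventional trunk values); both overridable in configuration.
DEFAULT_REGION_F: dict[str, float] = {"abdomen_pelvis": 0.015, "chest": 0.014}

# Linear no-threshold stochastic-risk slope: 5% additional probability of
# stochastic effects per sievert of effective dose.
RISK_PCT_PER_SV = 5.0


@dataclass(frozen=True)
class RegionCoefficients:
    """Region-specific DLP -> ED conversion coefficients."""

    f_by_region: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_F))

    def __post_init__(self) -> None:
        for region, f in self.f_by_region.items():
            if not f > 0:
                raise ConfigurationError(f"f coefficient for {region!r} must be > 0, got {f}")

    def f(self, region: str) -> float:
        try:
            return self.f_by_region[region]
        except KeyError:
            raise ConfigurationError(
                f"no f coefficient registered for region {region!r}; "
                f"known regions: {sorted(self.f_by_region)}"
            ) from None


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(name, f"must be > 0, got {value}")


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, weight(kg) / height(m)^2."""
    _require_positive("weight_kg", weight_kg)
    _require_positive("height_cm", height_cm)
    return weight_kg / (height_cm / 100.0) ** 2


def compute_deff(ap_mm: float, lat_mm: float) -> float:
    """Effective diameter in mm: geometric mean sqrt(AP * LAT)."""
    _require_positive("ap_mm", ap_mm)
    _require_positive("lat_mm", lat_mm)
    return math.sqrt(ap_mm * lat_mm)


def compute_ssde(ctdi_vol: float, k: float) -> float:
    """Size-specific dose estimate, CTDIvol * k, in mGy."""
    _require_positive("ctdi_vol", ctdi_vol)
    _require_positive("k", k)
    return ctdi_vol * k


def compute_ed(dlp: float, region: str, coeffs: RegionCoefficients | None = None) -> float:
    """Effective dose DLP * f(region), in mSv."""
    _require_positive("dlp", dlp)
    coeffs = coeffs or RegionCoefficients()
    return dlp * coeffs.f(region)


def compute_dlpss(dlp: float, k: float) -> float:
    """Size-specific dose-length product DLP * k, in mGy*cm."""
    _require_positive("dlp", dlp)
    _require_positive("k", k)
    return dlp * k


def compute_edss(dlp_ss: float, region: str, coeffs: RegionCoefficients | None = None) -> float:
    """Size-specific effective dose DLPss * f(region), in mSv."""
    _require_positive("dlp_ss", dlp_ss)
    coeffs = coeffs or RegionCoefficients()
    return dlp_ss * coeffs.f(region)


def percent_increase(new_value: float, old_value: float) -> float:
    """100 * (new - old) / old; the size-specific-vs-traditional % difference."""
    if not old_value > 0:
        raise ValidationError("old_value", f"must be > 0, got {old_value}")
    return 100.0 * (new_value - old_value) / old_value


def length_change(scan_length_mm: float, topogram_length_mm: float) -> float:
    """Diagnostic minus topogram scan length, mm (negative = range reduced)."""
    return scan_length_mm - topogram_length_mm


def ctdi_bias(deff_mm, model: ConversionModel | None = None):
    """Fractional under/over-estimation of SSDE by CTDIvol: 1 - 1/k.

    Positive for patients smaller than the k = 1 crossing (CTDIvol
    underestimates the size-specific dose), negative for larger patients
    (overestimation). Accepts scalars or arrays.
    """
    model = model or ConversionModel.aapm204_fit()
    return 1.0 - 1.0 / model.k(deff_mm)


def stochastic_risk_increment(ed_msv: float) -> float:
    """Added probability of stochastic effects, in %, for an ED in mSv.

    Linear no-threshold: 5% per Sv, so 10 mSv -> 0.05%.
    """
    if ed_msv < 0:
        raise ValidationError("ed_msv", f"must be >= 0, got {ed_msv}")
    return ed_msv / 1000.0 * RISK_PCT_PER_SV


def compute_all(
    record: ExamRecord,
    model: ConversionModel | None = None,
    coeffs: RegionCoefficients | None = None,
) -> DoseMetrics:
    """Full per-examination metric set for one validated record."""
    model = model or ConversionModel.aapm204_fit()
    coeffs = coeffs or RegionCoefficients()
    try:
        bmi = compute_bmi(record.weight, record.height)
        deff = compute_deff(record.ap, record.lat)
        k = model.k(deff)
        ssde = compute_ssde(record.ctdi_vol, k)
        ed = compute_ed(record.dlp, record.region, coeffs)
        dlp_ss = compute_dlpss(record.dlp, k)
        ed_ss = compute_edss(dlp_ss, record.region, coeffs)
        bias = 1.0 - 1.0 / k
    except SizedoseError as err:
        err.args = (f"exam {record.exam_id}: {err}",)
        raise
    change = length_change(record.scan_length, record.topogram_length)
    return DoseMetrics(
        exam_id=record.exam_id,
        bmi=bmi,
        deff=deff,
        k=k,
        ssde=ssde,
        ed=ed,
        dlp_ss=dlp_ss,
        ed_ss=ed_ss,
        ctdi_bias_fraction=bias,
        scan_length_change=change,
        scan_length_change_pct=100.0 * change / record.topogram_length,
    )


def metrics_frame(
    cohort: pd.DataFrame,
    model: ConversionModel | None = None,
    coeffs: RegionCoefficients | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`compute_all` over a cohort DataFrame.

    Expects the cohort CSV schema columns (see :mod:`sizedose.io`);
    returns one row per examination, indexed like the input, with the
    nine derived columns plus ``exam_id``, ``sex`` and ``region`` carried
    through for downstream stratification.
    """
    model = model or ConversionModel.aapm204_fit()
    coeffs = coeffs or RegionCoefficients()
    height_m = cohort["height_cm"].to_numpy(float) / 100.0
    bmi = cohort["weight_kg"].to_numpy(float) / height_m**2
    deff = np.sqrt(cohort["ap_mm"].to_numpy(float) * cohort["lat_mm"].to_numpy(float))
    k = model.k(deff)
    ctdi = cohort["ctdi_vol_mGy"].to_numpy(float)
    dlp = cohort["dlp_mGycm"].to_numpy(float)
    f = cohort["region"].map(coeffs.f).to_numpy(float)
    change = cohort["scan_length_mm"].to_numpy(float) - cohort["topogram_length_mm"].to_numpy(float)
    return pd.DataFrame(
        {
            "exam_id": cohort["exam_id"].to_numpy(),
            "sex": cohort["sex"].to_numpy(),
            "region": cohort["region"].to_numpy(),
            "bmi": bmi,
            "deff_mm": deff,
            "k": k,
            "ssde_mGy": ctdi * k,
            "ed_mSv": dlp * f,
            "dlp_ss_mGycm": dlp * k,
            "ed_ss_mSv": dlp * k * f,
            "ctdi_bias": 1.0 - 1.0 / k,
            "scan_length_change_mm": change,
        },
        index=cohort.index,
    )
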