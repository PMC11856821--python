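import numpy as np
import pandas as pd
import pytest

from sizedose import (
    CohortTable,
    ConversionModel,
    ExamRecord,
    RegionCoefficients,
    SimulationConfig,
    generate,
)
from sizedose.io import COHORT_COLUMNS


@pytest.fixture(scope="session")
def body32_fit() -> ConversionModel:
    return ConversionModel.aapm204_fit("body32")


@pytest.fixture(scope="session")
def body32_table() -> ConversionModel:
    return ConversionModel.aapm204_table("body32")


@pytest.fixture(scope="session")
def region_coeffs() -> RegionCoefficients:
    return RegionCoefficients()


@pytest.fixture()
def exam_record() -> ExamRecord:
    return ExamRecord(
        exam_id="EX001",
        sex="female",
        age=55.0,
        weight=70.0,
        height=165.0,
        ap=240.0,
        lat=350.0,
        topogram_length=480.0,
        scan_length=470.0,
        ctdi_vol=11.0,
        dlp=520.0,
    )


def make_cohort_df(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "exam_id": "EX",
        "sex": "female",
        "age_years": 50.0,
        "weight_kg": 70.0,
        "height_cm": 165.0,
        "ap_mm": 240.0,
        "lat_mm": 350.0,
        "topogram_length_mm": 480.0,
        "scan_length_mm": 470.0,
        "ctdi_vol_mGy": 11.0,
        "dlp_mGycm": 520.0,
        "region": "abdomen_pelvis",
        "phantom": "body32",
        "exclusion_flags": "",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["exam_id"] = f"EX{i:03d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out, columns=COHORT_COLUMNS)


@pytest.fixture()
def small_cohort() -> CohortTable:
    rng = np.random.default_rng(42)
    rows = []
    for i in range(6):
        rows.append(
            {
                "sex": "female" if i % 2 else "male",
                # ranges keep BMI inside the default [18, 35] inclusion window
                "weight_kg": float(rng.uniform(62, 88)),
                "height_cm": float(rng.uniform(160, 180)),
                "ap_mm": float(rng.uniform(200, 300)),
                "lat_mm": float(rng.uniform(300, 420)),
                "ctdi_vol_mGy": float(rng.uniform(7, 18)),
                "dlp_mGycm": float(rng.uniform(300, 900)),
            }
        )
    return CohortTable(df=make_cohort_df(rows))


@pytest.fixture(scope="session")
def default_synthetic() -> CohortTable:
    """One default-sized synthetic cohort, shared across tests."""
    return generate(SimulationConfig(), seed=20250927 % 2**31)
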