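"""Domain records: one CT examination and its derived dose metrics."""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ValidationError

SEXES = ("female", "male")
REGIONS = ("abdomen_pelvis", "chest")
PHANTOMS = ("body32", "head16")

# Fields that must be strictly positive on a valid record.
_POSITIVE_FIELDS = (
    "weight",
    "height",
    "ap",
    "lat",
    "topogram_length",
    "scan_length",
    "ctdi_vol",
    "dlp",
)


@dataclass(frozen=True)
class ExamRecord:
    """A single CT examination.

    Lengths and cross-section dimensions are in mm, weight in kg, height
    in cm, CTDIvol in mGy, DLP in mGy*cm. ``ap``/``lat`` are the
    anteroposterior and lateral dimensions measured on the largest
    transverse slice of the scanned volume.
    """

    exam_id: str
    sex: str
    age: float
    weight: float
    height: float
    ap: float
    lat: float
    topogram_length: float
    scan_length: float
    ctdi_vol: float
    dlp: float
    region: str = "abdomen_pelvis"
    phantom: str = "body32"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError("sex", f"must be one of {SEXES}, got {self.sex!r}", self.exam_id)
        if self.region not in REGIONS:
            raise ValidationError(
                "region", f"must be one of {REGIONS}, got {self.region!r}", self.exam_id
            )
        if self.phantom not in PHANTOMS:
            raise ValidationError(
                "phantom", f"must be one of {PHANTOMS}, got {self.phantom!r}", self.exam_id
            )
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(name, f"must be > 0, got {value}", self.exam_id)
        if self.age < 0:
            raise ValidationError("age", f"must be >= 0, got {self.age}", self.exam_id)
        # Trunk regions are dosed against the 32 cm body phantom.
        if self.region in ("abdomen_pelvis", "chest") and self.phantom != "body32":
            raise ValidationError(
                "phantom", f"region {self.region!r} requires the body32 phantom", self.exam_id
            )


@dataclass(frozen=True)
class DoseMetrics:
    """Derived per-examination dose quantities.

    ``ctdi_bias_fraction`` is the fractional underestimation of the
    size-specific dose by the phantom-referenced CTDIvol, 1 - 1/k:
    positive when CTDIvol underestimates (small patient, k > 1),
    negative when it overestimates (k < 1).
    """

    exam_id: str
    bmi: float  # kg/m^2
    deff: float  # mm
    k: float  # dimensionless
    ssde: float  # mGy
    ed: float  # mSv
    dlp_ss: float  # mGy*cm
    ed_ss: float  # mSv
    ctdi_bias_fraction: float
    scan_length_change: float  # mm, diagnostic - topogram
    scan_length_change_pct: float  # % of topogram length

    def as_dict(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
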