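"""Size-dependent CTDIvol -> SSDE conversion factors.

The conversion factor k maps a phantom-referenced CTDIvol to a
patient-size-specific dose. AAPM Report 204 tabulates k against the
effective diameter Deff for the two reference phantoms (32 cm "body",
16 cm "head") and parameterises each table with a single exponential,

    k(Deff) = a * exp(-b * Deff_cm),

which reproduces the tabulated values to within the printed precision.
Both representations are supported: the exponential fit (default) and
linear interpolation on a tabulated (deff_cm, k) grid, so a site can
substitute its own table (e.g. water-equivalent-diameter based) without
touching code.

k > 1 for patients smaller than the reference phantom: they absorb a
higher dose than the phantom-referenced CTDIvol suggests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RangeError

# AAPM Report 204 exponential-fit coefficients, per reference phantom,
# effective-diameter table (a dimensionless, b per cm).
AAPM204_FIT: dict[str, tuple[float, float]] = {
    "body32": (3.704369, 0.03671937),
    "head16": (1.874799, 0.03871313),
}

# AAPM 204 tabulates effective diameters from roughly 6 to 55 cm.
DEFAULT_VALID_RANGE_CM: tuple[float, float] = (6.0, 55.0)

_TABLE_RESOURCE = "aapm204_k.csv"


def load_k_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a (phantom, deff_cm, k) grid; defaults to the packaged file."""
    if path is None:
        with resources.files("sizedose.data").joinpath(_TABLE_RESOURCE).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = {"phantom", "deff_cm", "k"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"k table missing columns: {sorted(missing)}")
    return df


@dataclass(frozen=True)
class ConversionModel:
    """Phantom-specific k(Deff) model.

    Parameters
    ----------
    phantom : {"body32", "head16"}
        Reference phantom the CTDIvol was reported against.
    coeff_a, coeff_b : float
        Exponential-fit coefficients (``a`` dimensionless, ``b`` per cm).
    valid_deff_range_cm : (float, float)
        Effective-diameter interval over which the model is trusted.
    mode : {"fit", "table"}
        Evaluate the exponential or interpolate ``table_points``.
    table_points : ndarray of shape (n, 2), optional
        (deff_cm, k) pairs, required for ``mode="table"``.
    clamp : bool
        If True (default) diameters outside the validity range are clamped
        to the nearest edge with a warning; if False a :class:`RangeError`
        is raised.
    """

    phantom: str = "body32"
    coeff_a: float = AAPM204_FIT["body32"][0]
    coeff_b: float = AAPM204_FIT["body32"][1]
    valid_deff_range_cm: tuple[float, float] = DEFAULT_VALID_RANGE_CM
    mode: str = "fit"
    table_points: np.ndarray | None = field(default=None, repr=False)
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.coeff_a <= 0 or self.coeff_b <= 0:
            raise ConfigurationError("fit coefficients must be positive")
        lo, hi = self.valid_deff_range_cm
        if not lo < hi:
            raise ConfigurationError("validity range must be a nonempty interval")
        if self.mode not in ("fit", "table"):
            raise ConfigurationError(f"unknown conversion mode {self.mode!r}")
        if self.mode == "table":
            if self.table_points is None or len(self.table_points) < 2:
                raise ConfigurationError("table mode needs >= 2 (deff_cm, k) points")
            pts = np.asarray(self.table_points, dtype=float)
            if np.any(np.diff(pts[:, 0]) <= 0):
                raise ConfigurationError("table deff_cm must be strictly increasing")
            if np.any(np.diff(pts[:, 1]) >= 0):
                raise ConfigurationError("table k must be strictly decreasing in deff")
            object.__setattr__(self, "table_points", pts)

    @classmethod
    def aapm204_fit(cls, phantom: str = "body32", *, clamp: bool = True) -> "ConversionModel":
        """Exponential-fit model with the report's coefficients."""
        if phantom not in AAPM204_FIT:
            raise ConfigurationError(f"unknown phantom {phantom!r}")
        a, b = AAPM204_FIT[phantom]
        return cls(phantom=phantom, coeff_a=a, coeff_b=b, clamp=clamp)

    @classmethod
    def aapm204_table(
        cls,
        phantom: str = "body32",
        path: str | Path | None = None,
        *,
        clamp: bool = True,
    ) -> "ConversionModel":
        """Table-interpolation model from the packaged (or a site's) grid."""
        df = load_k_table(path)
        sub = df[df["phantom"] == phantom].sort_values("deff_cm")
        if sub.empty:
            raise ConfigurationError(f"no table entries for phantom {phantom!r}")
        a, b = AAPM204_FIT.get(phantom, (1.0, 1.0))
        pts = sub[["deff_cm", "k"]].to_numpy(float)
        return cls(
            phantom=phantom,
            coeff_a=a,
            coeff_b=b,
            valid_deff_range_cm=(float(pts[0, 0]), float(pts[-1, 0])),
            mode="table",
            table_points=pts,
            clamp=clamp,
        )

    @property
    def unity_deff_cm(self) -> float:
        """Effective diameter (cm) at which k = 1: ln(a)/b for the fit."""
        if self.mode == "fit":
            return math.log(self.coeff_a) / self.coeff_b
        pts = self.table_points
        return float(np.interp(-1.0, -pts[:, 1], pts[:, 0]))  # k decreasing

    def _check_range(self, deff_cm: np.ndarray) -> np.ndarray:
        lo, hi = self.valid_deff_range_cm
        out = (deff_cm < lo) | (deff_cm > hi)
        if np.any(out):
            if not self.clamp:
                bad = np.atleast_1d(deff_cm)[np.atleast_1d(out)]
                raise RangeError(
                    f"effective diameter {bad.min():.1f}-{bad.max():.1f} cm outside "
                    f"model validity range [{lo}, {hi}] cm"
                )
            warnings.warn(
                f"{int(np.sum(out))} effective diameter(s) outside [{lo}, {hi}] cm "
                "clamped to the model validity range",
                stacklevel=3,
            )
        return np.clip(deff_cm, lo, hi)

    def k(self, deff_mm):
        """Conversion factor for an effective diameter given in mm.

        Accepts scalars or arrays; scalar in, scalar out.
        """
        arr = np.asarray(deff_mm, dtype=float)
        if np.any(arr <= 0):
            raise RangeError("effective diameter must be positive")
        deff_cm = self._check_range(arr / 10.0)
        if self.mode == "fit":
            k = self.coeff_a * np.exp(-self.coeff_b * deff_cm)
        else:
            pts = self.table_points
            k = np.interp(deff_cm, pts[:, 0], pts[:, 1])
        return float(k) if np.isscalar(deff_mm) else k


def k_factor(deff_mm, model: ConversionModel | None = None):
    """k for a given effective diameter (mm) under ``model`` (default body32 fit)."""
    model = model or ConversionModel.aapm204_fit()
    return model.k(deff_mm)
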