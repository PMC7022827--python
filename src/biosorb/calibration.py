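"""Linear optical-density / concentration standard curve.

Dye concentrations are measured spectrophotometrically; a linear standard
curve OD = m*C + b maps concentration (mg/L) to optical density. This module
fits the curve by ordinary least squares, inverts it to back-calculate
concentrations, and round-trips it through CSV/JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidCurveError

CSV_COLUMNS = ("concentration_mg_per_L", "od")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear standard curve OD = slope * C + intercept.

    Parameters
    ----------
    slope : float
        Optical-density units per mg/L; positive for a valid dye curve.
    intercept : float
        Optical density at zero concentration (blank absorbance).
    r_squared : float
        Centered coefficient of determination of the fit.
    n_points : int
        Number of calibration points used.
    wavelength_nm : float or None
        Measurement wavelength. Metadata only; never enters computation.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    wavelength_nm: float | None = None

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_calibration(
    points: Iterable[tuple[float, float]] | pd.DataFrame,
    wavelength_nm: float | None = None,
) -> CalibrationCurve:
    """Fit the linear standard curve by ordinary least squares.

    ``points`` is an iterable of (concentration mg/L, optical density) pairs
    or a DataFrame with columns ``concentration_mg_per_L`` and ``od``.

    Raises
    ------
    DegenerateInputError
        If fewer than two distinct concentrations are supplied.
    """
    if isinstance(points, pd.DataFrame):
        conc = points[CSV_COLUMNS[0]].to_numpy(dtype=float)
        od = points[CSV_COLUMNS[1]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise DegenerateInputError("expected (concentration, od) pairs")
        conc, od = arr[:, 0], arr[:, 1]
    if len(np.unique(conc)) < 2:
        raise DegenerateInputError(
            "calibration needs at least 2 distinct concentrations"
        )
    design = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), *_ = np.linalg.lstsq(design, od, rcond=None)
    fitted = slope * conc + intercept
    rss = float(np.sum((od - fitted) ** 2))
    tss = float(np.sum((od - od.mean()) ** 2))
    r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(r2, 1.0)),
        n_points=int(conc.size),
        wavelength_nm=wavelength_nm,
    )


def concentration_to_od(concentration, curve: CalibrationCurve):
    """Forward map C -> OD (used by the synthetic generator)."""
    return curve.slope * np.asarray(concentration, dtype=float) + curve.intercept


def od_to_concentration(od, curve: CalibrationCurve, clamp_negative: bool = False):
    """Back-calculate concentration (mg/L) from optical density.

    Negative back-calculated concentrations (od below the blank) are
    reported as-is with a warning; pass ``clamp_negative=True`` to clip
    them to zero instead.

    Raises
    ------
    InvalidCurveError
        If the curve slope is zero (no inverse exists).
    """
    if curve.slope == 0:
        raise InvalidCurveError("cannot invert a calibration curve with zero slope")
    conc = (np.asarray(od, dtype=float) - curve.intercept) / curve.slope
    if np.any(conc < 0):
        if clamp_negative:
            conc = np.clip(conc, 0.0, None)
        else:
            warnings.warn(
                "back-calculated concentration below zero; possible calibration drift",
                stacklevel=2,
            )
    return conc if conc.ndim else float(conc)


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DegenerateInputError(f"calibration CSV missing columns: {sorted(missing)}")
    return df


def write_curve_json(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2, sort_keys=True) + "\n")


def read_curve_json(path: str | Path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(
        slope=d["slope"],
        intercept=d["intercept"],
        r_squared=d["r_squared"],
        n_points=d["n_points"],
    )
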