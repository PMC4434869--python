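"""Detector-linearity calibration from fluorescent-bead series.

Beads of known relative (nominal) intensity imaged at several photomultiplier
(PMT) voltages give one nominal-vs-measured regression per voltage; the
detection system is taken as linear up to the highest voltage at which every
fit at or below it reaches the R-squared threshold (default 0.99). Cell
measurements can then be checked against the measured bead limits at the
working voltage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import CtcemtError


class CalibrationError(CtcemtError):
    pass


@dataclass(frozen=True)
class CalibrationFit:
    """Per-voltage ordinary-least-squares fit of measured on nominal level."""

    pmt_voltage: float
    slope: float
    intercept: float
    r_squared: float


def fit_linearity(series: pd.DataFrame) -> list[CalibrationFit]:
    """OLS of measured intensity on nominal level, per PMT voltage.

    ``series`` needs columns ``pmt_voltage``, ``nominal_level``, ``measured``;
    replicates enter as individual points and fits are unweighted. Returns
    fits sorted by voltage. A voltage with fewer than 2 distinct nominal
    levels is a calibration error; a constant measured response yields slope 0
    and R-squared 0.
    """
    required = {"pmt_voltage", "nominal_level", "measured"}
    if missing := required - set(series.columns):
        raise CalibrationError(f"bead series missing columns: {sorted(missing)}")
    fits = []
    for voltage, grp in series.groupby("pmt_voltage", sort=True):
        x = grp["nominal_level"].to_numpy(dtype=float)
        y = grp["measured"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise CalibrationError(
                f"voltage {voltage}: need >=2 distinct nominal levels"
            )
        if np.ptp(y) == 0:
            fits.append(CalibrationFit(float(voltage), 0.0, float(y[0]), 0.0))
            continue
        res = stats.linregress(x, y)
        fits.append(
            CalibrationFit(
                float(voltage),
                float(res.slope),
                float(res.intercept),
                float(res.rvalue**2),
            )
        )
    return fits


def linear_range(fits: list[CalibrationFit], r2_min: float = 0.99) -> float | None:
    """Highest voltage V such that every fit at voltage <= V has R^2 >= r2_min.

    Returns ``None`` when even the lowest voltage fails the threshold.
    """
    if not fits:
        raise CalibrationError("no fits given")
    best = None
    for fit in sorted(fits, key=lambda f: f.pmt_voltage):
        if fit.r_squared >= r2_min:
            best = fit.pmt_voltage
        else:
            break
    return best


@dataclass(frozen=True)
class RangeCheck:
    """How a set of cell intensities sits inside the bead standard curve."""

    pmt_voltage: float
    lower: float
    upper: float
    n_total: int
    n_in_range: int
    out_of_range: tuple[float, ...]

    @property
    def fraction_in_range(self) -> float:
        return self.n_in_range / self.n_total if self.n_total else 1.0


def check_in_range(
    values: list[float] | np.ndarray, series: pd.DataFrame, voltage: float
) -> RangeCheck:
    """Fraction of cell intensity values inside the measured bead limits at a voltage."""
    at_v = series.loc[series["pmt_voltage"] == voltage, "measured"]
    if at_v.empty:
        raise CalibrationError(f"voltage {voltage} not present in bead series")
    lo, hi = float(at_v.min()), float(at_v.max())
    vals = np.asarray(values, dtype=float)
    inside = (vals >= lo) & (vals <= hi)
    return RangeCheck(
        pmt_voltage=float(voltage),
        lower=lo,
        upper=hi,
        n_total=int(vals.size),
        n_in_range=int(inside.sum()),
        out_of_range=tuple(float(v) for v in vals[~inside]),
    )
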