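"""Voltage dependence and action-spectrum analysis of pump photocurrents.

Pump currents have no reversal potential, so their voltage dependence is
summarized by normalizing each cell's current-voltage (I-V) relationship to
its value at 0 mV holding potential and regressing the normalized current on
voltage over the negative branch.  The resulting slope ``S_neg`` is reported
in units of 10^-3 per mV (a slope of 7.5 means the normalized current falls
by 0.6 between 0 and -80 mV).

The action spectrum divides the steady-state current at each stimulus
wavelength by the irradiance delivered at that wavelength, normalizes each
cell's sensitivities to their maximum, and averages across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IVSeries",
    "SnegEstimate",
    "SpectrumMeasurement",
    "RelativeSpectrum",
    "NegativeSlopeRegressor",
    "normalize_iv",
    "estimate_sneg",
    "action_spectrum",
]


@dataclass(frozen=True)
class IVSeries:
    """Per-voltage currents for one cell; must contain the 0 mV anchor."""

    voltage: np.ndarray
    current: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if v.ndim != 1 or v.shape != i.shape:
            raise ValueError("voltage and current must be 1-D of equal length")
        if np.unique(v).size != v.size:
            raise ValueError("one entry per voltage required")
        if not np.any(v == 0.0):
            raise ValueError("series must include the 0 mV holding potential")
        if self.normalized:
            i0 = i[v == 0.0][0]
            if not np.isclose(i0, 1.0):
                raise ValueError("normalized series must equal 1 at 0 mV")
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "current", i)


@dataclass(frozen=True)
class SnegEstimate:
    """OLS slope of the normalized I-V over the negative voltage branch."""

    slope: float  # in 10^-3 per mV
    intercept: float
    n_points: int


@dataclass(frozen=True)
class SpectrumMeasurement:
    wavelength: float  # nm, band center
    irradiance: float  # mW/mm^2
    i_ss: float  # pA/pF
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.irradiance <= 0:
            raise ValueError("irradiance must be positive")


@dataclass(frozen=True)
class RelativeSpectrum:
    wavelength: np.ndarray
    relative_sensitivity: np.ndarray
    peak_wavelength: float
    sem: np.ndarray | None = field(default=None)


def normalize_iv(series: IVSeries) -> IVSeries:
    """Express every current relative to the 0 mV value (idempotent)."""
    i0 = float(series.current[series.voltage == 0.0][0])
    if i0 == 0.0:
        raise ZeroDivisionError("current at 0 mV is zero; cannot normalize")
    return IVSeries(series.voltage, series.current / i0, normalized=True)


class NegativeSlopeRegressor(BaseEstimator):
    """OLS line through the negative-branch points of a normalized I-V.

    Parameters
    ----------
    include_zero : bool
        Whether the 0 mV anchor participates in the regression (default
        True; the normalized plots run to and through 0 mV).

    Attributes
    ----------
    slope_ : float
        Slope in 10^-3 per mV.
    intercept_ : float
    n_points_ : int
    """

    def __init__(self, include_zero: bool = True):
        self.include_zero = include_zero

    def fit(self, X, y):
        v = np.asarray(X, dtype=float).reshape(-1)
        i = np.asarray(y, dtype=float).reshape(-1)
        mask = v <= 0.0 if self.include_zero else v < 0.0
        if mask.sum() < 3:
            raise ValueError("need at least 3 negative-region points")
        res = stats.linregress(v[mask], i[mask])
        self.slope_ = float(res.slope) * 1e3
        self.intercept_ = float(res.intercept)
        self.n_points_ = int(mask.sum())
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        v = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * 1e-3 * v


def estimate_sneg(series: IVSeries, include_zero: bool = True) -> SnegEstimate:
    """Negative-branch slope of a normalized I-V, in 10^-3 per mV."""
    if not series.normalized:
        raise ValueError("series must be normalized first (normalize_iv)")
    est = NegativeSlopeRegressor(include_zero=include_zero).fit(
        series.voltage, series.current
    )
    return SnegEstimate(slope=est.slope_, intercept=est.intercept_, n_points=est.n_points_)


def action_spectrum(
    measurements: list[SpectrumMeasurement],
) -> tuple[dict[str, RelativeSpectrum], RelativeSpectrum]:
    """Irradiance-corrected relative action spectrum, per cell and averaged.

    Per cell: sensitivity(lambda) = i_ss(lambda) / irradiance(lambda),
    divided by its own maximum so each cell peaks at 1.  The cross-cell
    average (with SEM) is computed per wavelength on the per-cell normalized
    values; the peak wavelength is the argmax of the average.
    """
    if not measurements:
        raise ValueError("no measurements")
    df = pd.DataFrame(
        {
            "cell": [m.cell_id for m in measurements],
            "wavelength": [m.wavelength for m in measurements],
            "sensitivity": [m.i_ss / m.irradiance for m in measurements],
        }
    )
    if df.duplicated(["cell", "wavelength"]).any():
        raise ValueError("duplicate wavelength within a cell")

    per_cell: dict[str, RelativeSpectrum] = {}
    for cell, g in df.groupby("cell", sort=False):
        g = g.sort_values("wavelength")
        rel = g["sensitivity"].to_numpy()
        peak = rel.max()
        if peak <= 0:
            raise ValueError(f"cell {cell!r} has no positive sensitivity")
        rel = rel / peak
        wl = g["wavelength"].to_numpy()
        per_cell[cell] = RelativeSpectrum(
            wavelength=wl, relative_sensitivity=rel,
            peak_wavelength=float(wl[np.argmax(rel)]),
        )

    wavelengths = np.unique(df["wavelength"].to_numpy())
    stack = []
    for cell, spec in per_cell.items():
        if spec.wavelength.size != wavelengths.size or not np.array_equal(
            spec.wavelength, wavelengths
        ):
            raise ValueError("all cells must share the same wavelength grid")
        stack.append(spec.relative_sensitivity)
    mat = np.vstack(stack)
    mean = mat.mean(axis=0)
    sem = (
        mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros_like(mean)
    )
    average = RelativeSpectrum(
        wavelength=wavelengths, relative_sensitivity=mean,
        peak_wavelength=float(wavelengths[np.argmax(mean)]), sem=sem,
    )
    return per_cell, average
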