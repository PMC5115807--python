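"""Irradiance-response (dose-response) models for pump photocurrents.

A rhodopsin driven by single-photon photochemistry produces a photocurrent
that saturates with irradiance following a Michaelis-Menten (rectangular
hyperbola) law::

    y(x) = Imax * x / (x + K_D)

with ``x`` the irradiance in mW/mm^2, ``Imax`` the ceiling current density
(pA/pF) and ``K_D`` the half-saturation irradiance.  Some pumps additionally
show a power-dependent suppression of the steady-state current above a
threshold irradiance ``T``; the composite model subtracts a second hyperbola
that engages only above the threshold::

    y(x) = Imax * x/(x + K_D1) - A * (x - T)/((x - T) + K_D2)   for x > T

and equals the plain hyperbola at or below ``T``.

Both models are exposed as scikit-learn compatible regressors
(:class:`MichaelisMentenRegressor`, :class:`SuppressedMichaelisMentenRegressor`)
and as thin functional wrappers (:func:`fit_mm`, :func:`fit_suppressed_mm`,
:func:`fit_kd_restricted`) operating on :class:`DoseResponse` records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DoseResponse",
    "MMFit",
    "SuppressedMMFit",
    "MichaelisMentenRegressor",
    "SuppressedMichaelisMentenRegressor",
    "fit_mm",
    "fit_suppressed_mm",
    "fit_kd_restricted",
    "michaelis_menten",
    "suppressed_michaelis_menten",
    "summarize_fits",
]

KD_BOUNDS = (1e-3, 1e4)


def michaelis_menten(x, imax, kd):
    """Saturating hyperbola ``imax * x / (x + kd)``."""
    x = np.asarray(x, dtype=float)
    return imax * x / (x + kd)


def suppressed_michaelis_menten(x, imax, kd1, supp_amp, kd2, threshold=10.0):
    """Hyperbola minus a suppression hyperbola engaged above ``threshold``."""
    x = np.asarray(x, dtype=float)
    base = michaelis_menten(x, imax, kd1)
    excess = np.clip(x - threshold, 0.0, None)
    with np.errstate(invalid="ignore"):
        supp = np.where(excess > 0, supp_amp * excess / (excess + kd2), 0.0)
    return base - supp


@dataclass(frozen=True)
class DoseResponse:
    """Per-cell irradiance/response points (irradiances strictly positive)."""

    irradiance: np.ndarray
    response: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.irradiance, dtype=float)
        y = np.asarray(self.response, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("irradiance and response must be 1-D of equal length")
        if x.size == 0:
            raise ValueError("dose-response set must not be empty")
        if np.any(x <= 0):
            raise ValueError("irradiances must be strictly positive")
        object.__setattr__(self, "irradiance", x)
        object.__setattr__(self, "response", y)


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters for one cell."""

    imax: float
    kd: float
    residual_sse: float
    n_points: int = 0
    n_excluded: int = 0
    at_boundary: bool = False


@dataclass(frozen=True)
class SuppressedMMFit:
    """Fitted composite (suppression-subtracted) parameters for one cell."""

    imax: float
    kd1: float
    supp_amp: float
    threshold: float
    kd2: float
    residual_sse: float
    negative_model_values: bool = False


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of ``y = imax * x / (x + kd)``.

    Uses bounded trust-region least squares with multi-start initialization
    (``kd0`` at the half-response irradiance and at the median irradiance),
    keeping the best converged solution.

    Attributes
    ----------
    imax_ : float
        Fitted ceiling response (>= 0).
    kd_ : float
        Fitted half-saturation irradiance (within ``KD_BOUNDS``).
    residual_sse_ : float
        Residual sum of squares at the optimum.
    at_boundary_ : bool
        True when ``kd_`` landed on a bound (degenerate, e.g. constant data).
    """

    def __init__(self, imax_bound_factor: float = 10.0):
        self.imax_bound_factor = imax_bound_factor

    def _kd_starts(self, x: np.ndarray, y: np.ndarray) -> list[float]:
        starts = [float(np.median(x))]
        ymax = y.max()
        if ymax > 0:
            half = 0.5 * ymax
            idx = int(np.argmin(np.abs(y - half)))
            starts.insert(0, float(x[idx]))
        return [min(max(s, KD_BOUNDS[0]), KD_BOUNDS[1]) for s in starts]

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 distinct irradiances to fit")
        if np.any(x <= 0):
            raise ValueError("irradiances must be strictly positive")

        imax_hi = max(self.imax_bound_factor * max(y.max(), 0.0), 1e-6)
        best = None
        for kd0 in self._kd_starts(x, y):
            imax0 = min(max(y.max(), 1e-6), imax_hi)
            res = least_squares(
                lambda p: michaelis_menten(x, *p) - y,
                x0=[imax0, kd0],
                bounds=([0.0, KD_BOUNDS[0]], [imax_hi, KD_BOUNDS[1]]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise RuntimeError("Michaelis-Menten fit failed to converge from all starts")

        self.imax_, self.kd_ = (float(v) for v in best.x)
        self.residual_sse_ = float(2.0 * best.cost)
        self.at_boundary_ = bool(
            np.isclose(self.kd_, KD_BOUNDS[0]) or np.isclose(self.kd_, KD_BOUNDS[1])
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return michaelis_menten(x, self.imax_, self.kd_)


class SuppressedMichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Fit the suppression-subtracted composite model with fixed threshold.

    ``y = imax*x/(x+kd1) - supp_amp*(x-T)/((x-T)+kd2)`` for ``x > T``, the
    plain hyperbola otherwise.  ``T`` (``threshold``) is a given of the
    protocol, not a fitted parameter.

    Attributes: ``imax_``, ``kd1_``, ``supp_amp_``, ``kd2_``,
    ``residual_sse_``, ``negative_model_values_`` (fit-quality flag raised
    when the fitted composite dips below zero anywhere on the data range —
    never clamped silently).
    """

    def __init__(self, threshold: float = 10.0, imax_bound_factor: float = 10.0):
        self.threshold = threshold
        self.imax_bound_factor = imax_bound_factor

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(x).size < 5:
            raise ValueError("need at least 5 distinct irradiances to fit")
        if not (x > self.threshold).any():
            raise ValueError(
                "no points above the suppression threshold: suppression unidentifiable"
            )
        if not (x <= self.threshold).any():
            raise ValueError("need points at or below the threshold to anchor kd1")

        T = self.threshold
        ymax = max(y.max(), 1e-6)
        amp_hi = max(self.imax_bound_factor * ymax, 1e-6)
        lo = [0.0, KD_BOUNDS[0], 0.0, KD_BOUNDS[0]]
        hi = [amp_hi, KD_BOUNDS[1], amp_hi, KD_BOUNDS[1]]

        def resid(p):
            return suppressed_michaelis_menten(x, *p, threshold=T) - y

        kd1_starts = [float(np.median(x[x <= T])), float(np.median(x))]
        kd2_starts = [float(np.median(x[x > T]) - T) or 1.0, 4.0 * T]
        best = None
        for kd10 in kd1_starts:
            for kd20 in kd2_starts:
                x0 = [
                    ymax,
                    min(max(kd10, KD_BOUNDS[0]), KD_BOUNDS[1]),
                    0.5 * ymax,
                    min(max(kd20, KD_BOUNDS[0]), KD_BOUNDS[1]),
                ]
                res = least_squares(
                    resid, x0=x0, bounds=(lo, hi),
                    xtol=1e-13, ftol=1e-13, gtol=1e-13,
                )
                if res.success and (best is None or res.cost < best.cost):
                    best = res
        if best is None:
            raise RuntimeError("composite fit failed to converge from all starts")

        self.imax_, self.kd1_, self.supp_amp_, self.kd2_ = (float(v) for v in best.x)
        self.residual_sse_ = float(2.0 * best.cost)
        grid = np.linspace(x.min(), x.max(), 512)
        self.negative_model_values_ = bool(
            (suppressed_michaelis_menten(
                grid, self.imax_, self.kd1_, self.supp_amp_, self.kd2_, threshold=T
            ) < 0).any()
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "kd1_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return suppressed_michaelis_menten(
            x, self.imax_, self.kd1_, self.supp_amp_, self.kd2_, threshold=self.threshold
        )


def fit_mm(data: DoseResponse) -> MMFit:
    """Fit the plain Michaelis-Menten model to one cell's points."""
    est = MichaelisMentenRegressor().fit(data.irradiance, data.response)
    return MMFit(
        imax=est.imax_, kd=est.kd_, residual_sse=est.residual_sse_,
        n_points=data.irradiance.size, at_boundary=est.at_boundary_,
    )


def fit_suppressed_mm(data: DoseResponse, threshold: float = 10.0) -> SuppressedMMFit:
    """Fit the composite suppression-subtracted model (threshold fixed)."""
    est = SuppressedMichaelisMentenRegressor(threshold=threshold).fit(
        data.irradiance, data.response
    )
    return SuppressedMMFit(
        imax=est.imax_, kd1=est.kd1_, supp_amp=est.supp_amp_,
        threshold=threshold, kd2=est.kd2_, residual_sse=est.residual_sse_,
        negative_model_values=est.negative_model_values_,
    )


def fit_kd_restricted(data: DoseResponse, max_irradiance: float = 12.0) -> MMFit:
    """Michaelis-Menten fit restricted to irradiances <= ``max_irradiance``.

    Used for the steady-state current of pumps whose high-irradiance response
    is distorted by suppression: only the low-irradiance branch obeys the
    plain hyperbola.  Records how many points were excluded.
    """
    keep = data.irradiance <= max_irradiance
    n_excluded = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError(
            f"only {int(keep.sum())} points at or below {max_irradiance} mW/mm^2; need >= 3"
        )
    sub = DoseResponse(data.irradiance[keep], data.response[keep], data.cell_id)
    fit = fit_mm(sub)
    return MMFit(
        imax=fit.imax, kd=fit.kd, residual_sse=fit.residual_sse,
        n_points=int(keep.sum()), n_excluded=n_excluded, at_boundary=fit.at_boundary,
    )


def summarize_fits(fits: list[MMFit]) -> dict:
    """Mean +/- SEM of imax and kd across per-cell fits (n-cells convention)."""
    if not fits:
        raise ValueError("no fits to summarize")
    kd = np.array([f.kd for f in fits])
    imax = np.array([f.imax for f in fits])
    n = len(fits)
    sem = lambda a: float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "n": n,
        "kd_mean": float(kd.mean()), "kd_sem": sem(kd),
        "imax_mean": float(imax.mean()), "imax_sem": sem(imax),
    }
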