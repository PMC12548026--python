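"""Cumulative submission time series and growth-curve fitting.

Cumulative yearly record counts are fitted per technology: a logistic
``L / (1 + exp(-k (x - x0)))`` for microarray submissions (which have
saturated) and a cubic polynomial for RNA-seq.  The cubic is always fitted
on a *centered* year coordinate — published raw-year cubic coefficients at
two-decimal precision suffer catastrophic cancellation, so raw-basis
coefficients are derived outputs, never the fitting basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "EmptySeriesError",
    "TimeSeries",
    "LogisticFit",
    "CubicFit",
    "cumulative_by_year",
    "fit_logistic",
    "fit_cubic",
    "logistic_value",
    "inflection",
    "project_fold_change",
    "REFERENCE_MICROARRAY_LOGISTIC",
    "REFERENCE_RNASEQ_CUBIC_RAW",
]


class FitError(RuntimeError):
    pass


class EmptySeriesError(ValueError):
    pass


@dataclass
class TimeSeries:
    x: np.ndarray  # year values, strictly increasing (fractional allowed)
    y: np.ndarray  # cumulative counts, non-decreasing
    technology: str = "unknown"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) and np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if len(self.y) and np.any(np.diff(self.y) < 0):
            raise ValueError("cumulative counts must be non-decreasing")

    def __len__(self):
        return len(self.x)


def cumulative_by_year(records: Iterable, technology: Optional[str] = None) -> TimeSeries:
    """Yearly cumulative count of records by submission date.

    Records without a parseable date are skipped; *technology* filters on
    ``technology_hint``.  Raises :class:`EmptySeriesError` when nothing
    remains.
    """
    years = [
        r.submission_date.year
        for r in records
        if r.submission_date is not None
        and (technology is None or r.technology_hint == technology)
    ]
    if not years:
        raise EmptySeriesError(
            f"no dated records for technology={technology!r}"
        )
    lo, hi = min(years), max(years)
    xs = np.arange(lo, hi + 1, dtype=float)
    counts = np.zeros(len(xs))
    for y in years:
        counts[y - lo] += 1
    return TimeSeries(xs, np.cumsum(counts), technology or "all")


# ---------------------------------------------------------------------------
# logistic
# ---------------------------------------------------------------------------


def _logistic(x, L, k, x0):
    return L / (1.0 + np.exp(-k * (x - x0)))


@dataclass
class LogisticFit:
    L: float
    k: float
    x0: float
    r_squared: float = float("nan")

    def value(self, x):
        """Model value ``L / (1 + exp(-k (x - x0)))``; at ``x = x0`` this is
        exactly ``L / 2``, and the limit as x -> inf is ``L``."""
        return _logistic(np.asarray(x, dtype=float), self.L, self.k, self.x0)

    @property
    def asymptote(self) -> float:
        """Closed-form limit of the model value as x -> infinity."""
        return self.L

    def inflection(self) -> float:
        """Root of the second derivative; analytically equal to x0."""
        if self.k == 0:
            raise FitError("inflection undefined for k = 0")
        return self.x0


#: Reference fit of cumulative bacterial microarray submissions in GEO
#: (yearly series, 2000 to May 2025): R^2 = 0.999.
REFERENCE_MICROARRAY_LOGISTIC = LogisticFit(
    L=45293.79, k=0.3968, x0=2011.245, r_squared=0.999
)

#: Reference raw-year cubic for cumulative bacterial RNA-seq submissions
#: (a3, a2, a1, a0): R^2 = 0.992.  Printed at 2-decimal precision, these
#: coefficients are numerically unusable for evaluation (catastrophic
#: cancellation); kept for reporting only.
REFERENCE_RNASEQ_CUBIC_RAW = (7.25, -43578.00, 87367474.23, -58386137342.10)


def _r_squared(y, fitted) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def fit_logistic(series: TimeSeries) -> LogisticFit:
    """Nonlinear least squares of the three-parameter logistic.

    Initialization: L0 = 1.05 max(y), x0_0 = median(x), k0 = 0.5, with
    L, k constrained positive.  Raises :class:`FitError` on degenerate input
    (constant series) or non-convergence, with optimizer diagnostics.
    """
    if len(series) < 4:
        raise FitError(f"need >= 4 points, got {len(series)}")
    x, y = series.x, series.y
    if np.ptp(y) == 0:
        raise FitError("constant series: logistic parameters unidentifiable")
    p0 = (1.05 * float(np.max(y)), 0.5, float(np.median(x)))
    try:
        popt, _ = curve_fit(
            _logistic,
            x,
            y,
            p0=p0,
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on optimizer
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    L, k, x0 = (float(v) for v in popt)
    return LogisticFit(L, k, x0, _r_squared(y, _logistic(x, L, k, x0)))


def logistic_value(fit: LogisticFit, x) -> float:
    return float(fit.value(x))


def inflection(fit: LogisticFit) -> float:
    return fit.inflection()


# ---------------------------------------------------------------------------
# cubic
# ---------------------------------------------------------------------------


@dataclass
class CubicFit:
    a3: float
    a2: float
    a1: float
    a0: float
    center: float  # year offset of the centered coordinate
    r_squared: float = float("nan")

    def value(self, x):
        t = np.asarray(x, dtype=float) - self.center
        return ((self.a3 * t + self.a2) * t + self.a1) * t + self.a0

    def raw_coefficients(self) -> tuple:
        """(a3, a2, a1, a0) on the raw-year basis, via polynomial shift."""
        centered = npoly.Polynomial([self.a0, self.a1, self.a2, self.a3])
        shifted = centered(npoly.Polynomial([-self.center, 1.0]))
        coef = np.zeros(4)
        coef[: len(shifted.coef)] = shifted.coef
        return tuple(float(c) for c in coef[::-1])


def fit_cubic(series: TimeSeries) -> CubicFit:
    """Ordinary least squares cubic on the centered year coordinate."""
    if len(series) < 5:
        raise FitError(f"need >= 5 points, got {len(series)}")
    x, y = series.x, series.y
    center = float(np.mean(x))
    t = x - center
    design = np.vander(t, 4)  # columns t^3, t^2, t, 1
    if np.linalg.matrix_rank(design) < 4:
        raise FitError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a3, a2, a1, a0 = (float(c) for c in coef)
    fit = CubicFit(a3, a2, a1, a0, center)
    fit.r_squared = _r_squared(y, fit.value(x))
    return fit


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def project_fold_change(fit_a, fit_b, year_from: float, year_to: float) -> float:
    """Fold change of the summed model values between two years."""
    denom = float(fit_a.value(year_from)) + float(fit_b.value(year_from))
    if denom == 0.0:
        raise FitError("zero total at year_from: fold change undefined")
    num = float(fit_a.value(year_to)) + float(fit_b.value(year_to))
    return num / denom
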