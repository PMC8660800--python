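"""Shared ordinary-least-squares machinery for first-order decay fits.

Every half-life in the package — transcriptome-wide or targeted — comes from
the same closed-form simple linear regression of log abundance on time, so
both fitting modules call into this single implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LinearFit", "ols", "halflife_from_slope"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LinearFit:
    """Simple linear regression y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float
    n: int


def ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Closed-form OLS of y on x via the normal equations.

    R² is 1 - SS_res/SS_tot; for a constant response (SS_tot = 0) R² is NaN,
    since the coefficient of determination is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points for a line")
    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    dy = y - ybar
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("x values are all identical")
    sxy = float(dx @ dy)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(dy @ dy)
    if ss_tot == 0.0:
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    if n > 2 and sxx > 0:
        mse = ss_res / (n - 2)
        se = math.sqrt(mse / sxx)
    else:
        se = float("nan")
    return LinearFit(slope=slope, intercept=intercept, r_squared=r2,
                     stderr_slope=se, n=n)


def halflife_from_slope(slope: float) -> float:
    """t1/2 = ln 2 / -b for a decaying fit; +inf when the slope is >= 0."""
    if slope < 0:
        return LN2 / -slope
    return float("inf")
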