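"""First-order decay fits for targeted time series (qPCR, northern, western).

A chase series is normalized to a co-measured reference feature (18S rRNA
for mRNA chases, tubulin for CHX protein chases) and rescaled to 1 at t = 0,
then fitted with y = a * exp(b * t) by linear regression of the log ratios —
the same math path as the transcriptome-wide module, so both agree exactly
on identical inputs.  Half-lives beyond the observation window are reported
as censored bounds ("> T h"), never as point estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._regression import halflife_from_slope, ols

__all__ = ["AbundanceSeries", "ExpFit", "normalize_series", "fit_first_order"]


@dataclass
class AbundanceSeries:
    """Target and reference signals over a chase time course.

    Signals are arbitrary linear intensities; the reference is a feature
    untouched by the treatment (e.g. 18S rRNA under actD).  ``reference``
    may be None when the target signal is already normalized.
    """

    feature: str
    times_h: np.ndarray
    target: np.ndarray
    reference_signal: np.ndarray | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.reference_signal is not None:
            self.reference_signal = np.asarray(self.reference_signal, dtype=float)
            if self.reference_signal.shape != self.times_h.shape:
                raise ValueError("reference_signal length mismatch")
        if self.target.shape != self.times_h.shape:
            raise ValueError("target length mismatch")
        if np.unique(self.times_h).size != self.times_h.size:
            raise ValueError("times must be distinct")
        if self.times_h.size < 3:
            raise ValueError("need at least 3 timepoints")


@dataclass(frozen=True)
class ExpFit:
    """Fit of y = a * exp(b * t): a is the fitted t = 0 value, b per hour.

    ``censored`` is set when the half-life exceeds the observation window;
    such values should be reported as "> T h" (see ``report()``), not as
    point estimates.
    """

    a: float
    b: float
    halflife_h: float
    r_squared: float
    censored: bool
    window_h: float

    def report(self) -> str:
        if self.censored:
            return f"> {self.window_h:g} h"
        return f"{self.halflife_h:.2f} h"


def normalize_series(series: AbundanceSeries):
    """Target/reference ratios rescaled to 1 at t = 0.

    Returns ``(times, ratios)``.  Requires a t = 0 point and positive
    reference signal everywhere.
    """
    t = series.times_h
    if not (t == 0).any():
        raise ValueError("series has no t = 0 point")
    if series.reference_signal is not None:
        if (series.reference_signal <= 0).any():
            raise ValueError("reference signal must be positive at every point")
        ratio = series.target / series.reference_signal
    else:
        ratio = series.target.astype(float).copy()
    r0 = ratio[t == 0][0]
    if r0 <= 0:
        raise ValueError("ratio at t = 0 must be positive")
    return t, ratio / r0


def fit_first_order(times_h, ratios, method: str = "loglinear") -> ExpFit:
    """Fit y = a * exp(b * t) to a normalized chase series.

    ``method='loglinear'`` (default) is OLS of ln(ratio) on time with
    a = exp(intercept); ``'nls'`` refines that fit by nonlinear least
    squares on the linear scale.  Non-positive ratios are dropped for the
    log fit; at least 3 positive points are required.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(ratios, dtype=float)
    keep = np.isfinite(y) & (y > 0)
    t_pos, y_pos = t[keep], y[keep]
    if t_pos.size < 3:
        raise ValueError("fewer than 3 positive points")
    fit = ols(t_pos, np.log(y_pos))
    a, b = math.exp(fit.intercept), fit.slope
    r2 = fit.r_squared
    if method == "nls":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(lambda tt, aa, bb: aa * np.exp(bb * tt),
                            t_pos, y_pos, p0=(a, b), maxfev=10000)
        a, b = float(popt[0]), float(popt[1])
        resid = y_pos - a * np.exp(b * t_pos)
        ss_tot = float(((y_pos - y_pos.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else math.nan
    elif method != "loglinear":
        raise ValueError(f"unknown method {method!r}")
    halflife = halflife_from_slope(b)
    window = float(t.max())
    return ExpFit(a=a, b=b, halflife_h=halflife, r_squared=r2,
                  censored=halflife > window, window_h=window)
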