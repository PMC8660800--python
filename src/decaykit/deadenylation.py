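"""Deadenylation kinetics from gel line scans.

An in vitro deadenylation assay resolves reaction intermediates on a
denaturing polyacrylamide gel; a line scan of each lane gives intensity
against migration position.  The workflow here is: calibrate position to
poly(A) tail length from a marker lane, pick the most abundant intermediate
per time point (the background-subtracted global intensity maximum within
the calibrated region), and fit tail length against time by linear
regression over the pre-plateau window — the apparent deadenylation rate in
adenosines removed per minute (As/min).  Inhibition is expressed as the
fold-reduction of the apparent rate relative to a reference reaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from ._regression import ols
from .synthetic import LaneProfile  # shared lane container

__all__ = [
    "LaneProfile",
    "TailCalibration",
    "RateEstimate",
    "FoldInhibition",
    "calibrate",
    "subtract_background",
    "most_abundant_tail",
    "estimate_rate",
    "fold_inhibition",
]


@dataclass
class TailCalibration:
    """Strictly monotone mapping from migration position to total length (nt).

    Built by piecewise-linear interpolation between marker bands; outside the
    marker range the mapping is clamped to the marker endpoints (never
    extrapolated), and lengths are clamped to [0, max marker length].
    """

    positions: np.ndarray
    tails_nt: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.tails_nt = np.asarray(self.tails_nt, dtype=float)
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.tails_nt = self.tails_nt[order]
        if len(self.positions) < 2:
            raise ValueError("need at least 2 marker bands")
        d = np.diff(self.tails_nt)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("marker table is not strictly monotone")

    def position_to_tail(self, position) -> np.ndarray:
        # np.interp needs increasing xp; it clamps outside the range,
        # which is the desired no-extrapolation behaviour
        nt = np.interp(position, self.positions, self.tails_nt)
        return np.clip(nt, 0.0, float(self.tails_nt.max()))

    @property
    def region(self):
        return float(self.positions.min()), float(self.positions.max())


def calibrate(marker_table: pd.DataFrame) -> TailCalibration:
    """Build a :class:`TailCalibration` from a marker-band table with
    ``position`` and ``tail_nt`` columns (total lengths, body included)."""
    return TailCalibration(
        positions=marker_table["position"].to_numpy(),
        tails_nt=marker_table["tail_nt"].to_numpy(),
    )


def subtract_background(lane: LaneProfile, window: int | None = None) -> np.ndarray:
    """Rolling-minimum baseline subtraction, clamped at zero.

    The baseline is the rolling minimum of the trace (window defaults to a
    fifth of the scan), which removes lane-wide offsets without assuming a
    functional form.
    """
    n = lane.intensities.size
    if window is None:
        window = max(3, n // 5)
    baseline = minimum_filter1d(lane.intensities, size=window, mode="nearest")
    return np.clip(lane.intensities - baseline, 0.0, None)


def most_abundant_tail(
    lane: LaneProfile,
    cal: TailCalibration,
    body_nt: int = 7,
    background_window: int | None = None,
) -> float:
    """Tail length (As) of the most abundant intermediate in one lane.

    Takes the background-subtracted global intensity maximum within the
    calibrated region and maps its position to total length, minus the body
    (7-mer by default) to express the result in adenosines.  Exact intensity
    ties are broken toward the longer tail — the earlier intermediate — which
    is deterministic and, if anything, underestimates the rate.
    """
    signal = subtract_background(lane, window=background_window)
    lo, hi = cal.region
    in_region = (lane.positions >= lo) & (lane.positions <= hi)
    if not in_region.any():
        raise ValueError("calibrated region does not overlap the profile")
    pos = lane.positions[in_region]
    sig = signal[in_region]
    if not (sig > 0).any():
        raise ValueError("profile is all zero after background subtraction")
    peak = sig.max()
    tied = pos[sig == peak]
    tails = cal.position_to_tail(tied)
    nt = float(np.max(tails))  # tie -> longer tail
    return max(0.0, nt - body_nt)


@dataclass(frozen=True)
class RateEstimate:
    """Apparent deadenylation rate: -slope of tail (As) vs time (min)."""

    rate_As_per_min: float
    intercept_As: float
    r_squared: float
    stderr: float
    n_points: int

    def __str__(self) -> str:
        return f"{self.rate_As_per_min:.3g} As/min (R² = {self.r_squared:.3f})"


def estimate_rate(
    tail_series: pd.DataFrame,
    exclude_plateau: bool = True,
    plateau_tail_As: float = 1.0,
) -> RateEstimate:
    """OLS of most-abundant tail length on time; rate = -slope.

    ``tail_series`` has columns ``time_min`` and ``tail_As``.  By default the
    regression stops at the first point where the tail reaches
    ``plateau_tail_As`` or less (the substrate is fully deadenylated there;
    later lanes only flatten the slope).  At least 3 points must remain.
    A positive slope is reported as rate 0 with a warning.
    """
    df = tail_series.sort_values("time_min").reset_index(drop=True)
    if exclude_plateau:
        hit = np.flatnonzero(df["tail_As"].to_numpy() <= plateau_tail_As)
        if hit.size:
            df = df.iloc[: hit[0] + 1]  # keep the first fully-deadenylated lane
    if len(df) < 3:
        raise ValueError("fewer than 3 usable (pre-plateau) points")
    fit = ols(df["time_min"].to_numpy(), df["tail_As"].to_numpy())
    rate = -fit.slope
    if rate < 0:
        warnings.warn(
            f"positive tail-vs-time slope ({fit.slope:.3g}); reporting rate 0",
            stacklevel=2,
        )
        rate = 0.0
    return RateEstimate(
        rate_As_per_min=rate,
        intercept_As=fit.intercept,
        r_squared=fit.r_squared,
        stderr=fit.stderr_slope,
        n_points=fit.n,
    )


def lanes_to_tail_series(profiles, cal: TailCalibration, body_nt: int = 7,
                         background_window: int | None = None) -> pd.DataFrame:
    """Most-abundant tail per lane, as a ``time_min``/``tail_As`` table."""
    rows = [
        {
            "time_min": lane.time_min,
            "tail_As": most_abundant_tail(lane, cal, body_nt=body_nt,
                                          background_window=background_window),
        }
        for lane in profiles
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldInhibition:
    """Fold-reduction of the apparent rate: reference / test.

    When the test rate is indistinguishable from zero the fold is reported
    as a lower bound (reference / SE of the test rate) with ``bound`` set,
    never as infinity.
    """

    fold: float
    stderr: float
    bound: bool = False

    def __str__(self) -> str:
        if self.bound:
            return f"> {self.fold:.2f}-fold"
        return f"{self.fold:.2f} ± {self.stderr:.2f}-fold"


def fold_inhibition(reference: RateEstimate, test: RateEstimate) -> FoldInhibition:
    """Fold-reduction of the test reaction's apparent rate vs the reference.

    The standard error is propagated from both fits by the delta method:
    SE(f)/f = sqrt((SE_ref/ref)^2 + (SE_test/test)^2).
    """
    r, s = reference.rate_As_per_min, test.rate_As_per_min
    if r <= 0:
        raise ValueError("reference rate must be positive")
    if s <= 0:
        eps = test.stderr
        if not (eps and math.isfinite(eps) and eps > 0):
            raise ValueError("zero test rate with no usable standard error")
        return FoldInhibition(fold=r / eps, stderr=math.nan, bound=True)
    fold = r / s
    rel = 0.0
    for est in (reference, test):
        if math.isfinite(est.stderr):
            rel += (est.stderr / est.rate_As_per_min) ** 2
    return FoldInhibition(fold=fold, stderr=fold * math.sqrt(rel))
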