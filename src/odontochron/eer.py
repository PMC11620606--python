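"""Enamel extension rates (EER) along the EDJ and their smoothed trend.

Each chained segment covers an EDJ arc interval in a known number of
days, so its local EER is simply arc span / days (µm/day of ameloblast
recruitment). The noisy interval-wise rates are summarized by a
penalized cubic smoothing spline — the 1-D analogue of a thin-plate
spline — with the effective degrees of freedom picked from a grid by
generalized cross-validation (GCV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import solve

from .chronology import ChronologyResult

DEFAULT_DF_GRID = tuple(range(3, 13))

__all__ = [
    "EERInterval",
    "EERProfile",
    "TrendFit",
    "SmoothingSpline",
    "eer_profile",
    "smooth_trend",
    "mean_trend",
]


@dataclass(frozen=True)
class EERInterval:
    edj_arc_span: float   # µm of EDJ covered
    days: float
    eer: float            # µm/day
    mid_day: float        # interval midpoint on the chosen timeline


@dataclass
class EERProfile:
    """Interval-wise extension rates for one tooth.

    ``timeline`` is "birth" (mid_day relative to birth, negative =
    prenatal) when the neonatal line was datable, else "initiation".
    """

    section_id: str
    intervals: list[EERInterval]
    timeline: str                       # "birth" | "initiation"
    trend: Optional["TrendFit"] = None

    @property
    def total_edj_length(self) -> float:
        return float(sum(iv.edj_arc_span for iv in self.intervals))


@dataclass
class TrendFit:
    """Smoothed EER trend: fitted values on an even day grid."""

    grid_days: np.ndarray
    fitted: np.ndarray
    df: float                           # selected effective degrees of freedom
    lam: float                          # penalty achieving that df
    gcv: float
    spline: "SmoothingSpline" = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# natural cubic smoothing spline (Green & Silverman banded construction)
# ---------------------------------------------------------------------------


class SmoothingSpline:
    """Penalized natural cubic spline with exact effective-df control.

    Minimizes sum w_i (y_i - f(x_i))^2 + lam * Int f''(t)^2 dt over
    natural cubic splines with knots at the unique x values. Duplicate x
    values are pre-averaged with proportional weights, so the fit is a
    linear smoother with hat matrix S = (W + lam K)^{-1} W and effective
    df = tr(S); K annihilates affine functions, hence straight-line data
    are reproduced exactly for any lam.
    """

    def __init__(self, x, y, lam: float, weights=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
        xu, inv = np.unique(x, return_inverse=True)
        if len(xu) < 4:
            raise ValueError("need at least 4 distinct x values")
        wu = np.bincount(inv, weights=w)
        yu = np.bincount(inv, weights=w * y) / wu
        self.x = xu
        self.y = yu
        self.w = wu
        self.lam = float(lam)
        K = self._penalty_matrix(xu)
        A = np.diag(wu) + self.lam * K
        self.fitted = solve(A, wu * yu, assume_a="pos")
        self._hat_trace = float(np.trace(solve(A, np.diag(wu), assume_a="pos")))
        self._interp = CubicSpline(xu, self.fitted, bc_type="natural")
        rss = float(np.sum(wu * (yu - self.fitted) ** 2))
        n = float(np.sum(wu))
        self.rss = rss
        self.gcv = n * rss / (n - self._hat_trace) ** 2

    @staticmethod
    def _penalty_matrix(knots: np.ndarray) -> np.ndarray:
        h = np.diff(knots)
        n = len(knots)
        m = n - 2
        D = np.zeros((m, n))
        for i in range(m):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        B = np.zeros((m, m))
        for i in range(m):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < m:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        return D.T @ solve(B, D, assume_a="pos")

    @property
    def edf(self) -> float:
        """Effective degrees of freedom, tr of the hat matrix (2..n)."""
        return self._hat_trace

    def predict(self, xnew) -> np.ndarray:
        """Natural-spline evaluation (linear extrapolation beyond knots)."""
        xnew = np.atleast_1d(np.asarray(xnew, dtype=float))
        out = self._interp(np.clip(xnew, self.x[0], self.x[-1]))
        # natural spline: extend linearly with the boundary slope
        lo, hi = xnew < self.x[0], xnew > self.x[-1]
        if lo.any():
            out[lo] += self._interp(self.x[0], 1) * (xnew[lo] - self.x[0])
        if hi.any():
            out[hi] += self._interp(self.x[-1], 1) * (xnew[hi] - self.x[-1])
        return out

    @classmethod
    def with_df(cls, x, y, df: float, weights=None) -> "SmoothingSpline":
        """Fit with the penalty tuned (bisection in log lam) to a target edf."""
        n_unique = len(np.unique(np.asarray(x, dtype=float)))
        if not 2.0 <= df <= n_unique:
            raise ValueError(f"target df {df} outside [2, {n_unique}]")
        span = np.ptp(np.asarray(x, dtype=float))
        lo, hi = 1e-10 * span**3, 1e10 * span**3
        f = lambda lam: cls(x, y, lam, weights=weights).edf - df
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi / lo < 1 + 1e-10:
                break
        return cls(x, y, np.sqrt(lo * hi), weights=weights)


# ---------------------------------------------------------------------------


def eer_profile(result: ChronologyResult) -> EERProfile:
    """Interval-wise enamel extension rates from a chained chronology.

    One interval per segment: EER = EDJ arc span / segment days. The
    timeline is relative to birth when the NNL was datable.
    """
    birth = result.birth_cum_day
    shift = birth if birth is not None else 0.0
    intervals = []
    for seg in result.segments:
        if not seg.days > 0:
            raise ValueError(f"segment {seg.index}: non-positive duration {seg.days}")
        span = seg.edj_end_arc - seg.edj_start_arc
        intervals.append(
            EERInterval(
                edj_arc_span=span,
                days=seg.days,
                eer=span / seg.days,
                mid_day=0.5 * (seg.cum_days_start + seg.cum_days_end) - shift,
            )
        )
    return EERProfile(
        section_id=result.section_id,
        intervals=intervals,
        timeline="birth" if birth is not None else "initiation",
    )


def smooth_trend(
    profile_or_xy,
    df_grid: Sequence[float] = DEFAULT_DF_GRID,
    n_grid: int = 200,
) -> TrendFit:
    """Smoothed EER-vs-time trend with GCV-selected degrees of freedom.

    Accepts an :class:`EERProfile` or an ``(x, y)`` pair. For each df in
    ``df_grid`` that the data can support, the penalty is tuned to that
    effective df and the fit scored by GCV; the best-scoring df wins.
    Fitted values are returned on an even grid spanning the data.
    """
    if isinstance(profile_or_xy, EERProfile):
        x = np.array([iv.mid_day for iv in profile_or_xy.intervals])
        y = np.array([iv.eer for iv in profile_or_xy.intervals])
    else:
        x, y = map(np.asarray, profile_or_xy)
    if len(x) < 5:
        raise ValueError("need at least 5 intervals to smooth a trend")
    n_unique = len(np.unique(x))
    usable = [df for df in df_grid if df <= n_unique - 0.5]
    if not usable:
        raise ValueError(
            f"no df in {list(df_grid)} is below the number of distinct days ({n_unique})"
        )
    fits = [SmoothingSpline.with_df(x, y, df) for df in usable]
    best = int(np.argmin([f.gcv for f in fits]))
    spline = fits[best]
    grid = np.linspace(float(np.min(x)), float(np.max(x)), n_grid)
    trend = TrendFit(
        grid_days=grid,
        fitted=spline.predict(grid),
        df=usable[best],
        lam=spline.lam,
        gcv=spline.gcv,
        spline=spline,
    )
    if isinstance(profile_or_xy, EERProfile):
        profile_or_xy.trend = trend
    return trend


def mean_trend(profiles: Sequence[EERProfile], grid: np.ndarray) -> np.ndarray:
    """Pointwise mean of per-tooth smoothed trends on a common day grid.

    Each tooth contributes only over its own observed span (NaN
    elsewhere); the mean ignores NaNs.
    """
    rows = []
    for p in profiles:
        fit = p.trend if p.trend is not None else smooth_trend(p)
        x = np.array([iv.mid_day for iv in p.intervals])
        vals = fit.spline.predict(grid)
        vals[(grid < x.min()) | (grid > x.max())] = np.nan
        rows.append(vals)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack(rows), axis=0)
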