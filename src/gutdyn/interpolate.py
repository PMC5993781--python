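"""Cubic-spline interpolation of sampled time series onto a pseudo-day grid.

The spline uses the Forsythe-Malcolm-Moler ('fmm') end conditions: the third
derivative at each boundary is taken from the exact cubic through the four
points at that end of the series, which makes the interpolant exact for
global cubic polynomials and gives a sensible extrapolating cubic beyond the
data. Each infant's series is evaluated at ``n_points`` (365 by default)
equally spaced pseudo-days spanning its own first and last sampled day;
negative interpolated fractions are clipped to zero and each grid
composition is renormalized to sum to one.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_PSEUDO_DAYS = 365


class FmmSpline:
    """Piecewise-cubic interpolant with fmm end conditions.

    ``y`` may be 2-D (n_points x n_series); all series share the knot
    positions ``x``, so the tridiagonal solve is vectorized across columns.
    Evaluation outside [x[0], x[-1]] extrapolates with the boundary cubics.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        squeeze = y.ndim == 1
        if squeeze:
            y = y[:, None]
        n = len(x)
        if n < 2:
            raise ValueError("need at least 2 points")
        if y.shape[0] != n:
            raise ValueError("x and y lengths disagree")
        if not np.all(np.diff(x) > 0):
            raise ValueError("x must be strictly increasing")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite input")
        self.x = x
        self.y = y
        self._squeeze = squeeze
        self.b, self.c, self.d = _fmm_coefficients(x, y)

    def __call__(self, xout) -> np.ndarray:
        xout = np.asarray(xout, dtype=float)
        i = np.clip(np.searchsorted(self.x, xout, side="right") - 1, 0, len(self.x) - 1)
        dx = (xout - self.x[i])[:, None]
        out = self.y[i] + dx * (self.b[i] + dx * (self.c[i] + dx * self.d[i]))
        return out[:, 0] if self._squeeze else out


def _fmm_coefficients(x: np.ndarray, y: np.ndarray):
    """Solve for the piecewise-cubic coefficients (b, c, d) per knot.

    On [x[i], x[i+1]]: f(u) = y[i] + b[i]*h + c[i]*h^2 + d[i]*h^3, h = u-x[i].
    """
    n, m = y.shape
    if n == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        b = np.vstack([slope, slope])
        z = np.zeros((2, m))
        return b, z.copy(), z.copy()
    dx = np.diff(x)  # (n-1,)
    # tridiagonal system: diag, off-diagonal (x-only) and RHS (per series)
    diag = np.empty(n)
    rhs = np.zeros((n, m))
    slopes = np.diff(y, axis=0) / dx[:, None]
    diag[1:-1] = 2.0 * (dx[:-1] + dx[1:])
    rhs[1:-1] = slopes[1:] - slopes[:-1]
    diag[0] = -dx[0]
    diag[-1] = -dx[-1]
    if n > 3:
        r0 = (rhs[2] / (x[3] - x[1]) - rhs[1] / (x[2] - x[0]))
        rn = (rhs[n - 2] / (x[n - 1] - x[n - 3]) - rhs[n - 3] / (x[n - 2] - x[n - 4]))
        rhs[0] = r0 * dx[0] ** 2 / (x[3] - x[0])
        rhs[-1] = -rn * dx[-1] ** 2 / (x[n - 1] - x[n - 4])
    off = np.concatenate([dx, [dx[-1]]])  # off[i-1] couples rows i-1, i
    # forward elimination (multipliers depend on x only)
    diag_w = diag.copy()
    for i in range(1, n):
        t = off[i - 1] / diag_w[i - 1]
        diag_w[i] = diag_w[i] - t * off[i - 1]
        rhs[i] = rhs[i] - t * rhs[i - 1]
    c = np.empty((n, m))
    c[-1] = rhs[-1] / diag_w[-1]
    for i in range(n - 2, -1, -1):
        c[i] = (rhs[i] - off[i] * c[i + 1]) / diag_w[i]
    b = np.empty((n, m))
    d = np.empty((n, m))
    b[-1] = slopes[-1] + dx[-1] * (c[-2] + 2.0 * c[-1])
    b[:-1] = slopes - dx[:, None] * (c[1:] + 2.0 * c[:-1])
    d[:-1] = (c[1:] - c[:-1]) / dx[:, None]
    c = 3.0 * c
    d[-1] = d[-2]
    return b, c, d


@dataclasses.dataclass
class InfantSeries:
    """One infant's interpolated relative-abundance trajectories.

    ``values`` is a pseudo-day x feature grid (rows sum to 1);
    ``grid_days`` maps each of the pseudo-days to the real-valued day of
    life it represents on this infant's own axis.
    """

    infant_id: str
    grid_days: np.ndarray
    values: pd.DataFrame

    @property
    def pseudo_days(self) -> np.ndarray:
        return np.asarray(self.values.index)


def interpolate_infant(
    days,
    compositions: pd.DataFrame,
    n_points: int = N_PSEUDO_DAYS,
    grid: str = "per_infant",
    infant_id: str = "",
) -> InfantSeries:
    """Interpolate one infant's sampled compositions onto a pseudo-day grid.

    ``days`` are the sampled days of life, ``compositions`` the matching
    relative-abundance rows. Duplicate-day samples are averaged before
    fitting; at least 4 distinct days are required by the fmm end
    conditions. ``grid='per_infant'`` spaces ``n_points`` pseudo-days evenly
    over [first_day, last_day]; ``grid='calendar'`` evaluates at integer
    days 1..n_points, extrapolating with the boundary cubics where needed.
    Negative interpolated values are set to zero, then each grid row is
    renormalized to a composition.
    """
    days = np.asarray(days, dtype=float)
    values = compositions.to_numpy(dtype=float)
    if not (np.isfinite(days).all() and np.isfinite(values).all()):
        raise ValueError("non-finite input")
    if len(days) != len(values):
        raise ValueError("days and compositions lengths disagree")
    frame = pd.DataFrame(values, index=days).groupby(level=0).mean()
    uniq_days = frame.index.to_numpy(dtype=float)
    if len(uniq_days) < 4:
        raise ValueError(
            f"infant {infant_id!r}: {len(uniq_days)} distinct sampled days; "
            "the fmm end conditions need at least 4"
        )
    if grid == "per_infant":
        grid_days = np.linspace(uniq_days[0], uniq_days[-1], n_points)
    elif grid == "calendar":
        grid_days = np.arange(1, n_points + 1, dtype=float)
    else:
        raise ValueError(f"unknown grid {grid!r}")
    spline = FmmSpline(uniq_days, frame.to_numpy())
    interp = spline(grid_days)
    interp = np.clip(interp, 0.0, None)
    sums = interp.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError(f"infant {infant_id!r}: all-zero interpolated composition")
    interp /= sums[:, None]
    out = pd.DataFrame(
        interp,
        index=pd.RangeIndex(1, n_points + 1, name="pseudo_day"),
        columns=compositions.columns,
    )
    return InfantSeries(infant_id=infant_id, grid_days=grid_days, values=out)


def interpolate_cohort(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    n_points: int = N_PSEUDO_DAYS,
    grid: str = "per_infant",
) -> dict[str, InfantSeries]:
    """Interpolate every infant's series; returns an id-ordered mapping."""
    series: dict[str, InfantSeries] = {}
    for infant_id, sub in meta.loc[rel.index].groupby("infant_id", sort=True):
        order = sub.sort_values("day_since_birth").index
        series[str(infant_id)] = interpolate_infant(
            sub.loc[order, "day_since_birth"].to_numpy(),
            rel.loc[order],
            n_points=n_points,
            grid=grid,
            infant_id=str(infant_id),
        )
    return series
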