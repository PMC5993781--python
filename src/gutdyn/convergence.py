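"""Contemporaneous beta-diversity convergence across a cohort.

Every infant's composition series is interpolated onto a 365-point
pseudo-day grid; at each grid index the distance between every unordered
infant pair is computed ("contemporaneous" distances). Per-infant mean
profiles and their grand mean summarize how similar the cohort is at each
developmental moment, a fixed-df spline smooth of the grand mean locates
the window of accelerated convergence (the contiguous run of steep negative
derivative around the steepest descent), and the same machinery supports
taxon-convergence correlations and the twin-similarity test.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from skbio import TreeNode

from .beta import BranchTable
from .interpolate import InfantSeries
from .ordination import LinearFit, SmoothFit, smooth_fit

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_DAY = 54


def exclude_late_starters(meta: pd.DataFrame, cutoff_day: int = DEFAULT_CUTOFF_DAY):
    """Split infant ids into (retained, dropped) by first sampled day.

    Infants whose sampling only commenced on or after ``cutoff_day`` cannot
    contribute to the early part of the pseudo-day axis and are dropped.
    """
    first = meta.groupby("infant_id")["day_since_birth"].min().sort_index()
    dropped = [str(i) for i in first.index[first >= cutoff_day]]
    retained = [str(i) for i in first.index if str(i) not in dropped]
    if dropped:
        logger.info("excluding late starters (first day >= %d): %s", cutoff_day, dropped)
    if len(retained) < 2:
        raise ValueError(
            f"fewer than 2 infants start before day {cutoff_day}; nothing to compare"
        )
    return retained, dropped


@dataclasses.dataclass
class ConvergenceProfile:
    """Pairwise contemporaneous distances and their hierarchy of means.

    ``pairwise`` is pseudo-day x pair (columns "A|B"), ``per_infant_mean``
    is infant x pseudo-day (each infant's mean distance to all others),
    ``grand_mean`` the cohort average per pseudo-day. ``smooth`` and
    ``window`` are filled in by :func:`detect_window`.
    """

    pairwise: pd.DataFrame
    per_infant_mean: pd.DataFrame
    grand_mean: pd.Series
    metric: str
    smooth: SmoothFit | None = None
    window: tuple[float, float] | None = None

    @property
    def infant_ids(self) -> list[str]:
        return list(self.per_infant_mean.index)


def _series_matrix(series: dict[str, InfantSeries]):
    ids = list(series)
    if len(ids) < 2:
        raise ValueError("need at least 2 infants")
    first = series[ids[0]]
    features = list(first.values.columns)
    T = len(first.values)
    stack = np.empty((len(ids), T, len(features)))
    for i, inf in enumerate(ids):
        v = series[inf].values
        if list(v.columns) != features or len(v) != T:
            raise ValueError("infant series are not on a common feature set / grid length")
        stack[i] = v.to_numpy()
    return ids, features, stack, np.asarray(first.values.index)


def _pair_distance_series(
    xi: np.ndarray, xj: np.ndarray, metric: str,
    branch_table: BranchTable | None, alpha: float,
) -> np.ndarray:
    """Distance between two infants at every grid index (vectorized over T)."""
    if metric == "bray_curtis":
        num = np.abs(xi - xj).sum(axis=1)
        den = (xi + xj).sum(axis=1)
        return num / den
    if metric == "gunifrac":
        assert branch_table is not None
        mi = xi @ branch_table.leaf_matrix.T
        mj = xj @ branch_table.leaf_matrix.T
        s = mi + mj
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(s > 0, branch_table.lengths * np.where(s > 0, s, 1.0) ** alpha, 0.0)
            ratio = np.where(s > 0, np.abs(mi - mj) / np.where(s > 0, s, 1.0), 0.0)
        return (w * ratio).sum(axis=1) / w.sum(axis=1)
    raise ValueError(f"unknown metric {metric!r}")


def contemporaneous_distances(
    series: dict[str, InfantSeries],
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    alpha: float = 0.5,
) -> ConvergenceProfile:
    """Pairwise distances at every pseudo-day, with per-infant and grand means."""
    ids, features, stack, pseudo_days = _series_matrix(series)
    bt = None
    if metric == "gunifrac":
        if tree is None:
            raise ValueError("metric 'gunifrac' requires a tree")
        bt = BranchTable.from_tree(tree, features)
    pairs = list(combinations(range(len(ids)), 2))
    pairwise = np.empty((stack.shape[1], len(pairs)))
    for c, (i, j) in enumerate(pairs):
        pairwise[:, c] = _pair_distance_series(stack[i], stack[j], metric, bt, alpha)
    cols = [f"{ids[i]}|{ids[j]}" for i, j in pairs]
    pw = pd.DataFrame(pairwise, index=pd.Index(pseudo_days, name="pseudo_day"), columns=cols)
    per_infant = np.zeros((len(ids), stack.shape[1]))
    for c, (i, j) in enumerate(pairs):
        per_infant[i] += pairwise[:, c]
        per_infant[j] += pairwise[:, c]
    per_infant /= len(ids) - 1
    pim = pd.DataFrame(per_infant, index=pd.Index(ids, name="infant_id"), columns=pw.index)
    grand = pd.Series(pairwise.mean(axis=1), index=pw.index, name="grand_mean")
    return ConvergenceProfile(pairwise=pw, per_infant_mean=pim, grand_mean=grand, metric=metric)


def detect_window(
    profile: ConvergenceProfile, df: int = 9, slope_fraction: float = 0.1
) -> tuple[float, float] | None:
    """Locate the period of accelerated convergence on the grand-mean profile.

    The grand mean is smoothed with a ``df``-basis spline; with m the most
    negative fitted derivative, the window is the maximal contiguous grid
    run containing argmin(derivative) on which the derivative stays below
    ``slope_fraction * m`` (at least that fraction of the steepest descent).
    Returns (start_day, end_day) in pseudo-day units, or None when the
    profile never descends.
    """
    days = np.asarray(profile.grand_mean.index, dtype=float)
    fit = smooth_fit(days, profile.grand_mean.to_numpy(), df=df)
    profile.smooth = fit
    deriv = fit.derivative
    # the fitted derivative is one-sided at the grid boundary and its
    # variance inflates there; keep the search to interior grid points
    trim = max(1, round(0.03 * len(deriv)))
    lo_lim, hi_lim = trim, len(deriv) - 1 - trim
    interior = deriv[lo_lim : hi_lim + 1]
    m = interior.min()
    if m >= 0:
        profile.window = None
        return None
    mask = deriv < slope_fraction * m
    i0 = i1 = lo_lim + int(np.argmin(interior))
    while i0 > lo_lim and mask[i0 - 1]:
        i0 -= 1
    while i1 < hi_lim and mask[i1 + 1]:
        i1 += 1
    window = (float(fit.grid[i0]), float(fit.grid[i1]))
    profile.window = window
    logger.info("convergence window: pseudo-days %.0f-%.0f", *window)
    return window


def convergence_trend(profile: ConvergenceProfile) -> LinearFit:
    """OLS of the grand-mean distance on the pseudo-day index."""
    days = np.asarray(profile.grand_mean.index, dtype=float)
    fit = scipy.stats.linregress(days, profile.grand_mean.to_numpy())
    return LinearFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def otu_convergence_correlation(
    series: dict[str, InfantSeries],
    profile: ConvergenceProfile,
    otus,
    window: tuple[float, float],
) -> pd.DataFrame:
    """Correlate cohort-mean taxon abundances with the grand-mean distance.

    For each feature, the Pearson correlation (with two-sided p) between its
    cohort-mean relative abundance and the grand-mean distance is computed
    across the pseudo-days inside ``window`` (inclusive). Features with zero
    in-window variance get NaN with a warning.
    """
    ids, features, stack, pseudo_days = _series_matrix(series)
    lo, hi = window
    if lo >= hi:
        raise ValueError("window start must precede end")
    mask = (pseudo_days >= lo) & (pseudo_days <= hi)
    if not mask.any():
        raise ValueError("window contains no pseudo-days")
    grand = profile.grand_mean.to_numpy()[mask]
    cohort_mean = stack.mean(axis=0)[mask]  # (t_in_window, features)
    out = []
    col = {f: i for i, f in enumerate(features)}
    for otu in otus:
        if otu not in col:
            raise ValueError(f"feature {otu!r} not present in the series")
        v = cohort_mean[:, col[otu]]
        if np.ptp(v) == 0 or np.ptp(grand) == 0:
            logger.warning("zero variance in window for %s; correlation undefined", otu)
            out.append((otu, np.nan, np.nan))
            continue
        r, p = scipy.stats.pearsonr(v, grand)
        out.append((otu, float(r), float(p)))
    return pd.DataFrame(out, columns=["feature", "correlation", "p_value"]).set_index("feature")


@dataclasses.dataclass
class TwinComparison:
    """Twin-pair vs twin-to-others contemporaneous distance comparison.

    ``twin_pair_distances`` holds the 365 pseudo-day distances between the
    twins; ``twin_to_others`` holds, per twin, the per-pseudo-day mean
    distance to every non-twin infant. The test is a one-sided Welch t-test
    of twin-pair distances being smaller, with the pseudo-days treated as
    observations (their autocorrelation inflates the effective sample size;
    see the methods note).
    """

    twin_pair_distances: pd.Series
    twin_to_others: pd.DataFrame
    t_statistic: float
    p_value: float
    mean_difference: float


def twin_similarity_test(
    series: dict[str, InfantSeries],
    twin_a: str,
    twin_b: str,
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    alpha: float = 0.5,
) -> TwinComparison:
    """Compare the twins' mutual distances with their distances to the cohort."""
    ids, features, stack, pseudo_days = _series_matrix(series)
    for twin in (twin_a, twin_b):
        if twin not in ids:
            raise ValueError(f"twin {twin!r} not present in the series")
    others = [i for i in ids if i not in (twin_a, twin_b)]
    if not others:
        raise ValueError("need at least one non-twin infant")
    bt = None
    if metric == "gunifrac":
        if tree is None:
            raise ValueError("metric 'gunifrac' requires a tree")
        bt = BranchTable.from_tree(tree, features)
    pos = {inf: i for i, inf in enumerate(ids)}
    pair = _pair_distance_series(stack[pos[twin_a]], stack[pos[twin_b]], metric, bt, alpha)
    to_others = {}
    for twin in (twin_a, twin_b):
        acc = np.zeros(stack.shape[1])
        for other in others:
            acc += _pair_distance_series(stack[pos[twin]], stack[pos[other]], metric, bt, alpha)
        to_others[twin] = acc / len(others)
    pooled = np.concatenate([to_others[twin_a], to_others[twin_b]])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(pair, pooled, equal_var=False, alternative="less")
    idx = pd.Index(pseudo_days, name="pseudo_day")
    return TwinComparison(
        twin_pair_distances=pd.Series(pair, index=idx, name=f"{twin_a}|{twin_b}"),
        twin_to_others=pd.DataFrame(to_others, index=idx),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(pair.mean() - pooled.mean()),
    )
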