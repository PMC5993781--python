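"""Ordination and inference on distance matrices.

Non-metric MDS (Kruskal stress-1) with a pool-adjacent-violators monotone
regression core, PERMANOVA with seeded label permutations, ordinary
least-squares axis-vs-time regression, and fixed-degrees-of-freedom cubic
B-spline smooths standing in the role penalized additive models usually
play (the degrees of freedom are pinned rather than selected, which makes
the fit deterministic and dependency-light while reporting R-squared the
same way).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
import statsmodels.api as sm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# isotonic regression

def isotonic_fit(targets, weights=None) -> np.ndarray:
    """Least-squares non-decreasing fit by pool-adjacent-violators.

    Returns the non-decreasing sequence minimizing the weighted squared
    error to ``targets``; the weighted mean is preserved.
    """
    y = np.asarray(targets, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights length mismatch")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    # blocks of (weighted sum, weight, count)
    means: list[float] = []
    wsums: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        means.append(yi)
        wsums.append(wi)
        counts.append(1)
        while len(means) > 1 and means[-2] >= means[-1]:
            m2, w2, c2 = means.pop(), wsums.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wsums.pop(), counts.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wsums.append(wt)
            counts.append(c1 + c2)
    return np.repeat(means, counts)


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling

@dataclasses.dataclass
class NmdsResult:
    """An nMDS embedding: centered coordinates, Kruskal stress-1, diagnostics.

    Axis 1 is the coordinate dimension with the largest variance, its sign
    fixed so the correlation with sample index is non-negative.
    """

    coordinates: pd.DataFrame
    stress: float
    n_iterations: int
    converged: bool

    def axis(self, k: int = 1) -> pd.Series:
        return self.coordinates.iloc[:, k - 1]


def _classical_scaling(d: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    X = evecs[:, order] * np.sqrt(lam)
    flat = lam <= 1e-12 * max(lam.max(), 1.0)
    if flat.any():  # degenerate axes get a tiny seeded jitter so they can move
        X[:, flat] += rng.normal(scale=1e-6, size=(n, int(flat.sum())))
    return X


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _disparities(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    # primary tie handling: within blocks of tied dissimilarities the current
    # configuration distances set the order, favouring monotonicity
    order = np.lexsort((d, delta))
    dhat = np.empty_like(d)
    dhat[order] = isotonic_fit(d[order])
    return dhat


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NmdsResult:
    """Kruskal non-metric MDS of a distance matrix into ``k`` dimensions.

    Starts from the classical (metric) scaling of ``d`` and alternates
    monotone regression of configuration distances on the dissimilarity
    ranks with a Guttman majorization step, accepting a step only if
    stress-1 does not increase (with step halving otherwise), so stress is
    non-increasing across accepted iterations.
    """
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples, got {n}")
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    delta = squareform(D, checks=False)
    if np.all(delta == 0):
        raise ValueError("degenerate distance matrix (all zeros)")
    rng = np.random.default_rng(seed)
    X = _classical_scaling(D, k, rng)
    dcfg = pdist(X)
    dhat = _disparities(dcfg, delta)
    stress = _stress1(dcfg, dhat)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Guttman transform with the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dcfg > 0, dhat / dcfg, 0.0)
        R = squareform(ratio, checks=False)
        Bmat = -R
        np.fill_diagonal(Bmat, R.sum(axis=1))
        X_target = (Bmat @ X) / n
        accepted = False
        step = 1.0
        for _ in range(12):
            X_try = X + step * (X_target - X)
            d_try = pdist(X_try)
            dhat_try = _disparities(d_try, delta)
            s_try = _stress1(d_try, dhat_try)
            if s_try <= stress:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            converged = True
            break
        improvement = stress - s_try
        X, dcfg, dhat = X_try, d_try, dhat_try
        prev = stress
        stress = s_try
        if prev > 0 and improvement / prev < tol:
            converged = True
            break
    X = X - X.mean(axis=0)
    order = np.argsort(X.var(axis=0))[::-1]
    X = X[:, order]
    idx = np.arange(n)
    for j in range(k):
        if np.corrcoef(X[:, j], idx)[0, 1] < 0:
            X[:, j] = -X[:, j]
    coords = pd.DataFrame(
        X, index=list(d.ids), columns=[f"axis{i + 1}" for i in range(k)]
    )
    return NmdsResult(coordinates=coords, stress=stress, n_iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclasses.dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _ss_within_py(d2: np.ndarray, order: np.ndarray, bounds: np.ndarray) -> float:
    # sum of (1/n_g) * sum_{i<j in g} d^2 with groups as slices of `order`
    total = 0.0
    for g in range(len(bounds) - 1):
        lo, hi = bounds[g], bounds[g + 1]
        acc = 0.0
        for a in range(lo, hi):
            ia = order[a]
            for b in range(a + 1, hi):
                acc += d2[ia, order[b]]
        total += acc / (hi - lo)
    return total


try:
    from numba import njit as _njit

    _ss_within = _njit(cache=False)(_ss_within_py)
except ImportError:  # pragma: no cover
    _ss_within = _ss_within_py


def _permanova_stats(d2: np.ndarray, order: np.ndarray, bounds: np.ndarray, n: int):
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, order, bounds)
    ss_among = ss_total - ss_within
    a = len(bounds) - 1
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``groups`` is a label per sample, aligned with ``d.ids`` (a mapping or
    pandas Series keyed by id is also accepted). The p-value uses the
    add-one convention, (1 + #{permuted F >= observed F}) / (1 + permutations),
    so its resolution is 1/(n_permutations + 1) and it is never exactly 0.
    """
    ids = list(d.ids)
    n = len(ids)
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([groups[i] for i in ids])
    else:
        labels = np.asarray(groups)
        if len(labels) != n:
            raise ValueError("groups length does not match distance matrix")
    if n < 4:
        raise ValueError("need at least 4 samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        singletons = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups of size 1 are not allowed: {singletons}")
    d2 = np.asarray(d.data, dtype=float) ** 2
    # order samples by group; permuting labels uniformly is equivalent to
    # filling the fixed-size group slots with a random permutation of samples
    order_obs = np.concatenate([np.flatnonzero(labels == u) for u in uniq])
    bounds = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    f_obs, r2 = _permanova_stats(d2, order_obs.astype(np.int64), bounds, n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n).astype(np.int64)
        f_perm, _ = _permanova_stats(d2, perm, bounds, n)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), r_squared=float(r2), p_value=float(p),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# regressions

class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def axis_time_regression(result: NmdsResult, days) -> LinearFit:
    """OLS of the first nMDS axis on days since birth."""
    days = np.asarray(days, dtype=float)
    axis1 = result.axis(1).to_numpy()
    if len(days) != len(axis1):
        raise ValueError("days not aligned with samples")
    if len(days) < 3:
        raise ValueError("need at least 3 samples")
    if np.all(days == days[0]):
        raise ValueError("days are constant")
    fit = scipy.stats.linregress(days, axis1)
    return LinearFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


# ---------------------------------------------------------------------------
# fixed-df spline smooths

@dataclasses.dataclass
class SmoothFit:
    """An unpenalized cubic B-spline regression with ``df`` basis functions.

    ``grid`` holds the sorted distinct predictor values; fitted values,
    pointwise 95% bands (from the OLS covariance), the derivative of the
    fitted spline, and centered R-squared are reported on that grid.
    """

    grid: np.ndarray
    fitted: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    derivative: np.ndarray
    r_squared: float
    df: int
    knots: np.ndarray
    coefficients: np.ndarray

    def predict(self, x) -> np.ndarray:
        return BSpline(self.knots, self.coefficients, 3)(np.asarray(x, dtype=float))


def smooth_fit(x, y, df: int = 9) -> SmoothFit:
    """Fit y on a cubic B-spline basis of ``df`` functions of x.

    Interior knots sit at quantiles of the distinct predictor values; the
    fit is plain least squares, so it is deterministic and exact for any
    cubic polynomial (the basis spans cubics whenever df >= 4).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y lengths disagree")
    if df < 4:
        raise ValueError("df must be >= 4 for a cubic basis")
    ux = np.unique(x)
    if len(ux) < df + 1:
        raise ValueError(
            f"{len(ux)} distinct x values cannot support df={df}; use a smaller df"
        )
    order = 3
    n_interior = df - (order + 1)
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(ux, probs) if n_interior else np.array([])
    knots = np.concatenate([[ux[0]] * (order + 1), interior, [ux[-1]] * (order + 1)])
    design = BSpline.design_matrix(x, knots, order, extrapolate=True).toarray()
    model = sm.OLS(y, design).fit()
    coef = model.params
    cov = model.cov_params()
    spline = BSpline(knots, coef, order)
    grid = ux
    design_grid = BSpline.design_matrix(grid, knots, order, extrapolate=True).toarray()
    fitted = design_grid @ coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", design_grid, cov, design_grid))
    dof_resid = max(len(x) - df, 1)
    tcrit = scipy.stats.t.ppf(0.975, dof_resid)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if tss == 0 else 1.0 - (resid**2).sum() / tss
    return SmoothFit(
        grid=grid,
        fitted=fitted,
        lower95=fitted - tcrit * se,
        upper95=fitted + tcrit * se,
        derivative=spline.derivative()(grid),
        r_squared=float(r2),
        df=df,
        knots=knots,
        coefficients=coef,
    )
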