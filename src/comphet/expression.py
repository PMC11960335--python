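"""Temporal-expression profiling.

LOWESS smoothing (Cleveland's tricube-weighted local linear regression with
optional bisquare robustness passes) of age-indexed expression series per
brain region, and detection of expression peaks on the smoothed curve.

The smoother is implemented here in full rather than delegated, because the
analysis pins the textbook definition exactly: for each evaluation point the
``frac``-nearest neighbours get tricube distance weights, a weighted linear
fit is evaluated at the point, and robustness passes down-weight outliers by
the bisquare of residuals scaled by six times their median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)


@dataclass
class ExpressionSeries:
    """Expression (RPKM) of one region along a monotone developmental age
    axis (e.g. log post-conception days)."""

    region: str
    ages: np.ndarray
    rpkm: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        if self.ages.shape != self.rpkm.shape:
            raise ValueError("ages and rpkm must have the same length")
        if np.any(self.rpkm < 0):
            raise ValueError("rpkm must be non-negative")
        order = np.argsort(self.ages, kind="stable")
        self.ages, self.rpkm = self.ages[order], self.rpkm[order]

    def deduplicated(self) -> "ExpressionSeries":
        """Average replicate measurements at identical ages (with a warning)."""
        uniq, inverse, counts = np.unique(self.ages, return_inverse=True, return_counts=True)
        if len(uniq) == len(self.ages):
            return self
        logger.warning("%s: averaging %d duplicate ages", self.region, len(self.ages) - len(uniq))
        sums = np.zeros(len(uniq))
        np.add.at(sums, inverse, self.rpkm)
        return ExpressionSeries(self.region, uniq, sums / counts)


@dataclass
class SmoothedCurve:
    region: str
    grid: np.ndarray
    fitted: np.ndarray
    frac: float
    robust_iters: int

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.fitted):
            raise ValueError("grid/fitted length mismatch")
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("non-finite fitted value")


def _fit_at(x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float) -> float:
    """Weighted local-linear fit of (x, y) evaluated at x0."""
    sw = w.sum()
    if sw <= 0:
        return float(np.mean(y))
    xm = float((w * x).sum() / sw)
    ym = float((w * y).sum() / sw)
    sxx = float((w * (x - xm) ** 2).sum())
    # fall back to the weighted mean when the design is degenerate
    if sxx <= 1e-12 * max(1.0, float(np.var(x))) * sw:
        return ym
    slope = float((w * (x - xm) * (y - ym)).sum() / sxx)
    return ym + slope * (x0 - xm)


def lowess_smooth(
    series: ExpressionSeries,
    frac: float = 0.3,
    robust_iters: int = 0,
    grid: Optional[Sequence[float]] = None,
) -> SmoothedCurve:
    """LOWESS-smooth a series, evaluated at the observed ages or *grid*.

    ``frac`` is the fraction of points in each local neighbourhood
    (0 < frac <= 1); ``robust_iters`` bisquare re-weighting passes.  Requires
    at least three distinct ages; duplicate ages are averaged first.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    if robust_iters < 0:
        raise ValueError("robust_iters must be >= 0")
    series = series.deduplicated()
    x, y = series.ages, series.rpkm
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points to smooth")
    k = max(2, int(np.ceil(frac * n)))
    eval_x = x if grid is None else np.asarray(grid, dtype=float)

    robust_w = np.ones(n)
    fitted_obs = np.empty(n)
    for iteration in range(robust_iters + 1):
        for i in range(n):
            fitted_obs[i] = _local_fit(x, y, robust_w, k, x[i])
        if iteration == robust_iters:
            break
        resid = y - fitted_obs
        s = float(np.median(np.abs(resid)))
        if s <= 0:
            robust_w = np.ones(n)
        else:
            u = resid / (6.0 * s)
            robust_w = np.clip(1.0 - u * u, 0.0, None) ** 2

    fitted = (
        fitted_obs
        if grid is None
        else np.array([_local_fit(x, y, robust_w, k, x0) for x0 in eval_x])
    )
    return SmoothedCurve(series.region, eval_x, fitted, frac, robust_iters)


def _local_fit(x: np.ndarray, y: np.ndarray, robust_w: np.ndarray, k: int, x0: float) -> float:
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h <= 0:
        h = np.finfo(float).tiny
    u = np.clip(d / h, 0.0, 1.0)
    w = (1.0 - u**3) ** 3 * robust_w
    return _fit_at(x, y, w, x0)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_expression_peaks(curve: SmoothedCurve, min_prominence: Optional[float] = None) -> list[float]:
    """Ages of expression peaks on a smoothed curve, sorted by age.

    Interior local maxima with prominence >= ``min_prominence`` (default 10%
    of the curve's range) count, plus a boundary maximum whenever the curve
    rises into an endpoint by at least the prominence threshold — a plateau
    peak at the edge of the observed age range (e.g. adulthood) would
    otherwise be missed.
    """
    f = np.asarray(curve.fitted, dtype=float)
    if min_prominence is None:
        rng = float(f.max() - f.min())
        min_prominence = 0.1 * rng if rng > 0 else np.inf
    idx, _ = find_peaks(f, prominence=min_prominence)
    peaks = list(idx)
    # boundary maxima: rising into the edge by >= min_prominence since the
    # lowest point after (before) the nearest interior extremum
    if len(f) >= 2:
        if f[0] > f[1]:
            first_valley = f[: idx[0] + 1].min() if len(idx) else f.min()
            if f[0] - first_valley >= min_prominence:
                peaks.insert(0, 0)
        if f[-1] > f[-2]:
            last_valley = f[idx[-1]:].min() if len(idx) else f.min()
            if f[-1] - last_valley >= min_prominence:
                peaks.append(len(f) - 1)
    return [float(curve.grid[i]) for i in sorted(set(peaks))]
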