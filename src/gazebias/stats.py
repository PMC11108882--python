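"""Correlation and regression statistics for per-age mean biases.

For each fixation index and axis, the per-year mean biases are correlated
with age across the years present (n = number of age years, 61 for a full
5-65 design).  Pearson is the default method; Spearman (Pearson on midranks)
is available.  Two-sided p-values come from the t transform
``t = r * sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom, and 95%
confidence intervals from the Fisher z-transform,
``tanh(atanh(r) +/- z / sqrt(n-3))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from gazebias.pipeline import AgeAggregate
from gazebias.synthetic import AXES

logger = logging.getLogger(__name__)

Method = Literal["pearson", "spearman"]


class ZeroVarianceError(ValueError):
    """A correlation input vector is constant."""


class DegenerateDesignError(ValueError):
    """Regression predictor is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation of per-age mean bias with age for one fixation and axis."""

    fix_index: int
    axis: str
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    method: str


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary least-squares line fit: slope (dva/year) and intercept (dva)."""

    slope: float
    intercept: float
    n_points: int


def _validate_pair(x: np.ndarray, y: np.ndarray, min_n: int) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("x is constant: zero variance")
    if np.ptp(y) == 0:
        raise ZeroVarianceError("y is constant: zero variance")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two vectors (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y, 3)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation: Pearson r of midranks (ties get average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_pair(x, y, 3)
    return pearson_r(sps.rankdata(x), sps.rankdata(y))


def r_p_value(r: float, n: int, method: Method = "pearson") -> float:
    """Two-sided p-value for a correlation via the t transform on n-2 df.

    Used for both methods; for Spearman this is the usual large-sample
    approximation.  ``|r| = 1`` returns 0 by the exact-fit convention.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a p-value")
    if abs(r) >= 1.0:
        logger.info("|r| = 1: exact fit, p-value set to 0")
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation coefficient.

    ``tanh(atanh(r) +/- z_{(1+level)/2} / sqrt(n-3))``; requires n >= 4.
    At ``|r| = 1`` the z-transform diverges and the degenerate interval
    ``[r, r]`` is returned with a warning.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher z interval")
    if abs(r) >= 1.0:
        logger.warning("|r| = 1: degenerate confidence interval [r, r]")
        return (r, r)
    z = sps.norm.ppf((1.0 + level) / 2.0)
    half = z / math.sqrt(n - 3)
    zr = math.atanh(r)
    return (math.tanh(zr - half), math.tanh(zr + half))


def ols_slope(x: Sequence[float], y: Sequence[float]) -> SlopeFit:
    """Least-squares slope and intercept of y on x (x non-constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, length >= 2")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant x: degenerate design")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    return SlopeFit(slope=slope, intercept=intercept, n_points=x.size)


def correlate_by_fixation(
    agg: AgeAggregate, method: Method = "pearson"
) -> list[CorrelationResult]:
    """Correlate per-age mean bias with age for every fixation and axis.

    One :class:`CorrelationResult` per (fixation index, axis); n is the
    number of age years in the aggregate (must be >= 4).  A constant bias
    column (no variation across ages) raises :class:`ZeroVarianceError`
    noting that no association is computable there.
    """
    ages = np.asarray(agg.ages, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 distinct ages to correlate")
    corr_fn = pearson_r if method == "pearson" else spearman_rho
    results: list[CorrelationResult] = []
    for f in range(agg.n_fixations):
        for k, axis in enumerate(AXES):
            col = agg.matrix[:, f, k]
            try:
                r = corr_fn(ages, col)
            except ZeroVarianceError as exc:
                raise ZeroVarianceError(
                    f"no association computable for fixation {f + 1} ({axis}): {exc}"
                ) from exc
            n = ages.size
            ci_low, ci_high = fisher_ci(r, n)
            results.append(
                CorrelationResult(
                    fix_index=f + 1,
                    axis=axis,
                    r=r,
                    p=r_p_value(r, n, method),
                    ci_low=ci_low,
                    ci_high=ci_high,
                    n=n,
                    method=method,
                )
            )
    return results


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Report table: fix_index, axis, method, r, p, ci_low, ci_high, n."""
    return pd.DataFrame(
        [
            {
                "fix_index": r.fix_index,
                "axis": r.axis,
                "method": r.method,
                "r": r.r,
                "p": r.p,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n": r.n,
            }
            for r in results
        ]
    )
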