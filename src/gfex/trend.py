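"""Size trends of GFE measures and boxplot-based atypical-genome detection.

A measure (p.i., ave, mp or rank) is regressed on genome size with
polynomials of degree 1–10; the degree is selected by AIC (or BIC) under
the Gaussian-likelihood convention ``n·ln(RSS/n) + penalty·(degree + 2)``,
counting the residual-variance parameter.  Genomes are then flagged as
atypical when their residual from the selected trend falls outside the
boxplot whiskers ``[max(min r, Q1 − 1.5·IQR), min(max r, Q3 + 1.5·IQR)]``.

The predictor is centered and scaled internally (condition-number control
for degree-10 Vandermonde systems); coefficients are reported in both the
internal and the raw Mbp power basis.  A piecewise-linear fit with a
grid-searched breakpoint is available as an alternative description of
trends that change slope between small and large genomes.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TrendFit",
    "OutlierReport",
    "PiecewiseLinearFit",
    "fit_trend",
    "fit_piecewise_linear",
    "detect_outliers",
    "tukey_hinges",
]

# an RSS this small (per point) is numerically a perfect fit; taking its log
# would be meaningless, so model selection short-circuits to the smallest
# such degree
_PERFECT_RSS_PER_POINT = 1e-12


@dataclasses.dataclass
class TrendFit:
    """A selected polynomial trend of one measure against genome size."""

    degree: int
    coefficients: np.ndarray          # raw power basis, x in Mbp, ascending
    scaled_coefficients: np.ndarray   # internal mapped-domain basis
    domain: tuple[float, float]
    criterion: str
    aic: float
    bic: float
    rss: float
    n: int
    n_dropped: int
    score_by_degree: dict[int, float]
    fitted: dict[str, float]
    residuals: dict[str, float]
    band_95: pd.DataFrame             # columns x, fitted, lower, upper

    _poly: Polynomial = dataclasses.field(repr=False, default=None)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self._poly(np.asarray(x, dtype=float))


def _criterion_score(n: int, rss: float, degree: int, penalty: float) -> float:
    # degree + 1 coefficients plus the Gaussian variance parameter
    return n * np.log(rss / n) + penalty * (degree + 2)


def fit_trend(
    x: Sequence[float],
    y: Sequence[float],
    degrees: Iterable[int] = range(1, 11),
    criterion: str = "aic",
    ids: Optional[Sequence[str]] = None,
) -> TrendFit:
    """Fit polynomials of each candidate degree and keep the criterion winner.

    Pairs with a missing (NaN) response — e.g. genomes whose mp is undefined
    — are dropped with a logged count and can never appear in the residual
    map.  The sweep requires ``n ≥ max(degrees) + 2`` points; pass a
    narrower degree range for smaller samples.  Criterion ties go to the
    smaller degree (parsimony).
    """
    degrees = sorted(set(int(d) for d in degrees))
    if not degrees or degrees[0] < 1:
        raise ValueError("degrees must be a nonempty collection of integers >= 1")
    if criterion.lower() not in {"aic", "bic"}:
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    criterion = criterion.lower()

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    ids = [str(i) for i in (ids if ids is not None else range(len(x)))]
    if len(ids) != len(x):
        raise ValueError("ids must match the number of points")

    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_trend: dropped %d point(s) with missing values", n_dropped)
    x, y = x[keep], y[keep]
    ids = [g for g, k in zip(ids, keep) if k]

    n = len(x)
    if n < degrees[-1] + 2:
        raise ValueError(
            f"insufficient points: n={n} but the degree sweep up to "
            f"{degrees[-1]} needs at least {degrees[-1] + 2}"
        )
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: genome sizes are all identical")

    penalty = 2.0 if criterion == "aic" else float(np.log(n))
    fits: dict[int, tuple[Polynomial, float]] = {}
    scores: dict[int, float] = {}
    best_degree: int | None = None
    for d in degrees:
        poly = Polynomial.fit(x, y, d)
        rss = float(((y - poly(x)) ** 2).sum())
        fits[d] = (poly, rss)
        if rss <= _PERFECT_RSS_PER_POINT * n:
            # numerically exact fit: smaller degrees could not achieve it,
            # larger ones cannot improve it
            scores[d] = -np.inf
            best_degree = d
            break
        scores[d] = _criterion_score(n, rss, d, penalty)
    if best_degree is None:
        best_degree = min(scores, key=lambda d: (scores[d], d))

    poly, rss = fits[best_degree]
    fitted = poly(x)
    residuals = y - fitted
    aic = _criterion_score(n, rss, best_degree, 2.0) if rss > 0 else -np.inf
    bic = _criterion_score(n, rss, best_degree, float(np.log(n))) if rss > 0 else -np.inf

    band = _confidence_band(x, poly, rss, best_degree)
    return TrendFit(
        degree=best_degree,
        coefficients=poly.convert().coef,
        scaled_coefficients=poly.coef,
        domain=(float(poly.domain[0]), float(poly.domain[1])),
        criterion=criterion,
        aic=float(aic),
        bic=float(bic),
        rss=rss,
        n=n,
        n_dropped=n_dropped,
        score_by_degree=scores,
        fitted={g: float(v) for g, v in zip(ids, fitted)},
        residuals={g: float(v) for g, v in zip(ids, residuals)},
        band_95=band,
        _poly=poly,
    )


def _confidence_band(x: np.ndarray, poly: Polynomial, rss: float, degree: int) -> pd.DataFrame:
    """Pointwise 95% confidence bounds for the mean curve at the sample x."""
    n = len(x)
    p = degree + 1
    # design matrix in the fitted (mapped) domain
    t = (x - poly.domain[0]) / (poly.domain[1] - poly.domain[0]) * 2 - 1
    V = np.vander(t, p, increasing=True)
    dof = max(n - p, 1)
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(V.T @ V)
    se = np.sqrt(np.maximum((V @ xtx_inv * V).sum(axis=1), 0.0) * sigma2)
    tq = stats.t.ppf(0.975, dof)
    fitted = poly(x)
    order = np.argsort(x, kind="stable")
    return pd.DataFrame(
        {
            "x": x[order],
            "fitted": fitted[order],
            "lower": (fitted - tq * se)[order],
            "upper": (fitted + tq * se)[order],
        }
    )


# -- piecewise-linear alternative -----------------------------------------

@dataclasses.dataclass(frozen=True)
class PiecewiseLinearFit:
    breakpoint: float
    left_intercept: float
    left_slope: float
    right_intercept: float
    right_slope: float
    rss: float
    n_left: int
    n_right: int

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        left = self.left_intercept + self.left_slope * x
        right = self.right_intercept + self.right_slope * x
        return np.where(x <= self.breakpoint, left, right)


def fit_piecewise_linear(
    x: Sequence[float],
    y: Sequence[float],
    breakpoint_grid: Sequence[float],
    min_per_segment: int = 4,
) -> PiecewiseLinearFit:
    """Two independent regression lines joined at a grid-searched breakpoint.

    For every candidate breakpoint with at least ``min_per_segment`` points
    on each side, both segments are fit by least squares; the configuration
    with the smallest total RSS wins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(list(breakpoint_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty breakpoint grid")
    best: PiecewiseLinearFit | None = None
    for b in grid:
        left = x <= b
        right = ~left
        if left.sum() < min_per_segment or right.sum() < min_per_segment:
            continue
        if np.ptp(x[left]) == 0 or np.ptp(x[right]) == 0:
            continue
        cl = np.polynomial.polynomial.polyfit(x[left], y[left], 1)
        cr = np.polynomial.polynomial.polyfit(x[right], y[right], 1)
        rss = float(
            ((y[left] - (cl[0] + cl[1] * x[left])) ** 2).sum()
            + ((y[right] - (cr[0] + cr[1] * x[right])) ** 2).sum()
        )
        if best is None or rss < best.rss:
            best = PiecewiseLinearFit(
                breakpoint=float(b),
                left_intercept=float(cl[0]),
                left_slope=float(cl[1]),
                right_intercept=float(cr[0]),
                right_slope=float(cr[1]),
                rss=rss,
                n_left=int(left.sum()),
                n_right=int(right.sum()),
            )
    if best is None:
        raise ValueError(
            f"no breakpoint leaves >= {min_per_segment} points in both segments"
        )
    return best


# -- boxplot outlier detection --------------------------------------------

def tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """Quartiles by Tukey's hinges.

    The median splits the sorted sample into halves that *include* the
    median itself when n is odd; the hinges are the medians of the halves.
    This is the convention classic boxplots use.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    half = (n + 1) // 2
    return float(np.median(v[:half])), float(np.median(v)), float(np.median(v[n - half:]))


@dataclasses.dataclass
class OutlierReport:
    """Boxplot summary of trend residuals and the flagged atypical genomes."""

    q1: float
    q2: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: set[str]
    sides: dict[str, str]  # genome_id -> "above" | "below"


def detect_outliers(
    residuals: Mapping[str, float], quartile_method: str = "hinges"
) -> OutlierReport:
    """Flag genomes whose residual falls outside the boxplot whiskers.

    ``quartile_method='hinges'`` uses Tukey hinges (default);
    ``'linear'`` uses linear-interpolation quantiles for comparison.
    """
    ids = list(residuals)
    values = np.asarray([residuals[g] for g in ids], dtype=float)
    if len(values) < 5:
        raise ValueError(f"need at least 5 residuals for boxplot analysis, got {len(values)}")
    if not np.all(np.isfinite(values)):
        raise ValueError("residuals must be finite")
    if quartile_method == "hinges":
        q1, q2, q3 = tukey_hinges(values)
    elif quartile_method == "linear":
        q1, q2, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    else:
        raise ValueError(f"unknown quartile method {quartile_method!r}")
    iqr = q3 - q1
    upper = min(float(values.max()), q3 + 1.5 * iqr)
    lower = max(float(values.min()), q1 - 1.5 * iqr)
    sides = {}
    for g, v in zip(ids, values):
        if v > upper:
            sides[g] = "above"
        elif v < lower:
            sides[g] = "below"
    return OutlierReport(
        q1=q1,
        q2=q2,
        q3=q3,
        iqr=iqr,
        lower_whisker=lower,
        upper_whisker=upper,
        outliers=set(sides),
        sides=sides,
    )
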