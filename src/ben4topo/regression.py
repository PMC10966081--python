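"""Logarithmic and power regression of entropy on topological indices.

The relationship between an index series X and its entropy series Y over
growing BeN4 patches is curvilinear; the working model is the
log-linear form

    Y = beta0 + beta1 * ln(X) + eps,

fitted by ordinary least squares (natural logarithm -- the convention
under which the reference goodness tables reproduce).  A power model
``Y = a * X**b`` is available for comparison; it is fitted as OLS of
ln(Y) on ln(X), so its goodness statistics live on the log-log scale.

Goodness statistics follow curve-estimation conventions: R (correlation,
carrying the slope's sign), R^2, residual standard error
``SE = sqrt(RSS / (n - 2))``, the model F statistic with (1, n - 2)
degrees of freedom, and its upper-tail p value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .entropy import DIAGONAL_GRID, entropy_series
from .indices import INDEX_NAMES, compute_index, published_value
from .structure import ben4_edge_partition

__all__ = ["FitResult", "PowerFitResult", "log_fit", "power_fit", "index_series", "goodness_table"]


@dataclass(frozen=True)
class FitResult:
    """OLS fit of y on ln(x) with curve-estimation goodness statistics."""

    beta0: float  # intercept, y units
    beta1: float  # slope, y units per ln-x unit
    R: float      # correlation, sign of the slope
    R2: float
    SE: float     # residual standard error sqrt(RSS/(n-2))
    F: float
    p: float
    n_points: int


@dataclass(frozen=True)
class PowerFitResult:
    """Power-law fit y = a * x**b, estimated on the log-log scale."""

    a: float
    b: float
    R: float
    R2: float   # on the log-log scale
    SE: float   # residual SE of ln(y) on ln(x)
    F: float
    p: float
    n_points: int


def _ols_stats(ln_x: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, sm.add_constant(ln_x)).fit()
    beta0, beta1 = float(res.params[0]), float(res.params[1])
    r2 = float(res.rsquared)
    se = math.sqrt(float(res.scale))  # scale = RSS / (n - 2)
    f = float(res.fvalue)
    p = float(res.f_pvalue)
    r = math.copysign(math.sqrt(max(r2, 0.0)), beta1) if beta1 != 0 else math.sqrt(max(r2, 0.0))
    return beta0, beta1, r, r2, se, f, p


def _validate_xy(x, y, positive_y: bool = False):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("all x must be > 0 (logarithm of x is taken)")
    if positive_y and np.any(y <= 0):
        raise ValueError("all y must be > 0 for the power model")
    if np.all(x == x[0]):
        raise ValueError("x is constant; the fit is degenerate")
    return x, y


def log_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit of ``y = beta0 + beta1 * ln(x)``."""
    x, y = _validate_xy(x, y)
    beta0, beta1, r, r2, se, f, p = _ols_stats(np.log(x), y)
    return FitResult(beta0, beta1, r, r2, se, f, p, int(x.size))


def power_fit(x: Sequence[float], y: Sequence[float]) -> PowerFitResult:
    """Fit ``y = a * x**b`` via OLS of ln(y) on ln(x)."""
    x, y = _validate_xy(x, y, positive_y=True)
    beta0, beta1, r, r2, se, f, p = _ols_stats(np.log(x), np.log(y))
    return PowerFitResult(math.exp(beta0), beta1, r, r2, se, f, p, int(x.size))


def index_series(
    name: str,
    grid: Iterable[tuple[int, int]] = DIAGONAL_GRID,
    mode: str = "published",
    freq33: int | Callable[[int, int], int] | None = None,
) -> pd.Series:
    """Index values over a grid of (m, n) points, in either mode.

    Note the *index* series in published mode does not depend on
    ``freq33`` (the polynomial is evaluated verbatim); the parameter
    matters in canonical mode only.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if mode == "published":
        values = [published_value(name, m, n) for m, n in grid]
    elif mode == "canonical":
        values = [
            compute_index(
                ben4_edge_partition(m, n, freq33=(freq33(m, n) if callable(freq33) else freq33) if freq33 is not None else None),
                name,
            )
            for m, n in grid
        ]
    else:
        raise ValueError(f"mode must be 'canonical' or 'published', got {mode!r}")
    return pd.Series(values, index=pd.Index(grid, tupleize_cols=False), name=name)


def goodness_table(
    grid: Iterable[tuple[int, int]] = DIAGONAL_GRID,
    mode: str = "published",
    freq33: int | Callable[[int, int], int] | None = None,
    names: Sequence[str] = INDEX_NAMES,
) -> pd.DataFrame:
    """Log-fit goodness table: one row per index.

    For each index, fits entropy = beta0 + beta1 * ln(index) over the
    grid on the full-precision recomputed series (never the rounded
    display values) and reports beta1, beta0, R, R2, SE, F, p.

    ``freq33`` is forwarded to the entropy series (and, in canonical
    mode, the index series); the reference goodness tabulation is
    reproduced with ``freq33=reconciled_freq33``.
    """
    grid = list(grid)
    rows = {}
    for name in names:
        x = index_series(name, grid, mode=mode, freq33=freq33)
        y = entropy_series(name, grid, mode=mode, freq33=freq33)
        fit = log_fit(x.to_numpy(), y.to_numpy())
        rows[name] = {
            "beta1": fit.beta1, "beta0": fit.beta0, "R": fit.R, "R2": fit.R2,
            "SE": fit.SE, "F": fit.F, "p": fit.p,
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["beta1", "beta0", "R", "R2", "SE", "F", "p"])
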