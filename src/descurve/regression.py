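"""Ordinary least squares and single-breakpoint segmented regression.

The segmented model fits two line segments joined continuously at an
unknown breakpoint psi, via the basis {1, x, max(0, x - psi)}. psi is found
by profiling the residual sum of squares: a grid over the interior observed
x values locates the best region, then golden-section search refines psi
inside the bracketing interval. Because the basis nests the plain straight
line, the segmented SSE can never exceed the OLS SSE on the same data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OlsFit", "BreakpointFit", "ols_fit", "segmented_fit", "hinge_sse"]


@dataclass(frozen=True)
class OlsFit:
    slope: float
    intercept: float
    r_squared: float
    p_value_slope: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class BreakpointFit:
    psi: float
    left_slope: float
    right_slope: float
    intercept: float
    sse: float
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.left_slope * x
            + (self.right_slope - self.left_slope) * np.maximum(0.0, x - self.psi)
        )


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def ols_fit(x, y) -> OlsFit:
    """Closed-form simple linear regression with a two-sided slope t-test.

    Requires at least three finite points and non-constant x; the p-value
    uses the t distribution with n - 2 degrees of freedom.
    """
    x, y = _clean_xy(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a regression")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant; slope is undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    sse = syy - slope * sxy
    # constant y: nothing to explain, report zero explained variance
    r_squared = 0.0 if syy == 0.0 else max(0.0, 1.0 - sse / syy)
    if sse <= 0.0:
        p_value = 0.0 if slope != 0.0 else 1.0
    else:
        se = math.sqrt(sse / (n - 2) / sxx)
        t_stat = slope / se
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))
    return OlsFit(
        slope=float(slope),
        intercept=intercept,
        r_squared=float(r_squared),
        p_value_slope=p_value,
        n=n,
    )


def hinge_sse(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    """Residual SSE of the continuous two-segment model at a fixed breakpoint."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _hinge_coefs(x, y, psi):
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _golden_minimize(f, a, b, tol=1e-10, max_iter=200):
    """Plain golden-section minimization of f on [a, b]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    xm = (a + b) / 2.0
    return xm, f(xm)


def segmented_fit(x, y, exclude_zero_y: bool = False, min_per_side: int = 3) -> BreakpointFit:
    """Fit a continuous two-segment regression with one estimated breakpoint.

    ``exclude_zero_y`` drops points with y == 0 before fitting (undefined
    ratios, stored as NaN, are always dropped). Candidate breakpoints are
    the interior observed x values with at least ``min_per_side`` points
    strictly on each side; the grid winner is refined by golden-section
    search between its neighbouring candidates. Ties on the grid go to the
    earliest breakpoint.

    If all y are equal the model is degenerate: the plain OLS line is
    returned (both slopes equal) with a warning.
    """
    x, y = _clean_xy(x, y)
    if exclude_zero_y:
        keep = y != 0.0
        x, y = x[keep], y[keep]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)

    xs = np.unique(x)
    candidates = [
        float(v) for v in xs
        if (x < v).sum() >= min_per_side and (x > v).sum() >= min_per_side
    ]
    if not candidates:
        raise ValueError(
            f"need at least {min_per_side} points on each side of a breakpoint"
        )

    if np.all(y == y[0]):
        warnings.warn(
            "all y values equal; breakpoint is unidentifiable, returning a flat fit",
            stacklevel=2,
        )
        mid = float(np.median(candidates))
        return BreakpointFit(
            psi=mid, left_slope=0.0, right_slope=0.0,
            intercept=float(y[0]), sse=0.0, n=n,
        )

    sses = np.array([hinge_sse(x, y, psi) for psi in candidates])
    # refine around the best few grid candidates; ties go to the earliest psi
    order = np.argsort(sses, kind="stable")[: min(3, len(candidates))]
    best_i = int(order[0])
    psi, sse = candidates[best_i], float(sses[best_i])
    for i in order:
        lo = candidates[max(i - 1, 0)]
        hi = candidates[min(i + 1, len(candidates) - 1)]
        if hi <= lo:
            continue
        p, s = _golden_minimize(lambda p: hinge_sse(x, y, p), lo, hi)
        if s < sse - 1e-12 * (1.0 + abs(sse)) or (
            abs(s - sse) <= 1e-12 * (1.0 + abs(sse)) and p < psi
        ):
            psi, sse = p, s

    coef, sse = _hinge_coefs(x, y, psi)
    return BreakpointFit(
        psi=float(psi),
        left_slope=float(coef[1]),
        right_slope=float(coef[1] + coef[2]),
        intercept=float(coef[0]),
        sse=float(sse),
        n=n,
    )
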