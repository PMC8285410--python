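"""Robust simple linear regression by iteratively reweighted least squares.

Used for the per-participant similarity→RT regressions, where a handful of
lapse trials (very long RTs) would dominate an ordinary least-squares
slope.  Default weight function is Tukey's bisquare with tuning constant
4.685 (95% Gaussian efficiency); Huber (1.345) is available as an
alternative.  The residual scale is re-estimated each iteration as the
normalized median absolute deviation, MAD / 0.6745.
"""

from __future__ import annotations

import numpy as np

from ..types import DegenerateDataError

_TUNING = {"bisquare": 4.685, "huber": 1.345}


def _weights(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "bisquare":
        w = np.zeros_like(u)
        inside = np.abs(u) < 1.0
        w[inside] = (1.0 - u[inside] ** 2) ** 2
        return w
    if kind == "huber":
        au = np.abs(u)
        return np.where(au <= 1.0, 1.0, 1.0 / np.maximum(au, 1e-300))
    raise ValueError(f"unknown weight function {kind!r}")


def robust_line(
    x: np.ndarray,
    y: np.ndarray,
    weight: str = "bisquare",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Robust (intercept, slope) fit of y on x.  See :func:`robust_slope`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise DegenerateDataError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("predictor is constant")
    tune = _TUNING[weight] if weight in _TUNING else float(weight)

    X = np.column_stack([np.ones_like(x), x])
    # OLS start
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        resid = y - X @ coef
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            # exact fit (or > half the residuals identical): weights undefined
            break
        u = resid / (tune * scale)
        w = _weights(u, weight if weight in _TUNING else "bisquare")
        if w.sum() == 0 or np.ptp(x[w > 0]) == 0:
            break
        WX = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - coef)) < tol * max(1.0, np.max(np.abs(coef))):
            coef = new
            break
        coef = new
    return float(coef[0]), float(coef[1])


def robust_slope(x, y, weight: str = "bisquare", min_points: int = 5) -> float:
    """Robust slope of y on x (ms per similarity unit in the RT analyses).

    Raises :class:`DegenerateDataError` for constant x or fewer than
    ``min_points`` observations (callers exclude that participant and log).
    """
    x = np.asarray(x, dtype=float)
    if x.size < min_points:
        raise DegenerateDataError(f"need >= {min_points} points, got {x.size}")
    return robust_line(x, y, weight=weight)[1]
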