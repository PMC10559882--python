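"""Forecast evaluation suite.

MAPE, squared-correlation R2, accuracy growth rate between two models'
MAPEs, the Diebold-Mariano test of equal predictive accuracy (with the
standard-normal two-sided critical values 1.645 / 1.96 / 2.58 at the 90 /
95 / 99% confidence levels), and residual-variance stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

#: Two-sided standard-normal critical values keyed by confidence level.
DM_CRITICAL_VALUES = {0.90: 1.645, 0.95: 1.96, 0.99: 2.58}


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    return y, yhat


def mape(y, yhat) -> float:
    """Mean absolute percentage error, in percent.

    Raises on any zero truth rather than silently excluding it: dropping
    points changes N and corrupts cross-model comparisons.  Encoded series
    are bounded away from zero by construction (spectral values lie in
    [1, 4]), so the error only fires on misuse.
    """
    y, yhat = _pair(y, yhat)
    if y.size == 0:
        raise ValueError("mape needs at least one point")
    if np.any(y == 0):
        raise ZeroDivisionError("mape undefined: a true value is exactly zero")
    return float(np.mean(np.abs((y - yhat) / y)) * 100.0)


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between truths and forecasts.

    Affine-invariant and symmetric in its arguments; undefined (raises) when
    either input is constant.
    """
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("r_squared needs at least two points")
    dy = y - y.mean()
    dz = yhat - yhat.mean()
    denom = (dy @ dy) * (dz @ dz)
    if denom == 0.0:
        raise ValueError("r_squared undefined for a constant input")
    return float((dy @ dz) ** 2 / denom)


def accuracy_growth(mape_i: float, mape_j: float) -> float:
    """Relative accuracy growth rate |MAPE_i - MAPE_j| / MAPE_i, in percent."""
    if mape_i == 0:
        raise ZeroDivisionError("accuracy growth undefined for zero reference MAPE")
    return float(abs(mape_i - mape_j) / mape_i * 100.0)


@dataclass(frozen=True)
class DmResult:
    """Diebold-Mariano statistic and significance decisions."""

    statistic: float
    critical_values: tuple[float, float, float]  # at 90 / 95 / 99%
    reject_90: bool
    reject_95: bool
    reject_99: bool


def dm_test(
    errors_1,
    errors_2,
    loss: Literal["squared", "absolute"] = "squared",
    horizon: int = 1,
    harvey_correction: bool = False,
) -> DmResult:
    """Diebold-Mariano test for equal predictive accuracy.

    The loss differential d_t = L(e1_t) - L(e2_t) is averaged and scaled by
    the square root of its long-run (HAC) variance estimate using a
    rectangular window of horizon-1 autocovariance lags.  The statistic is
    compared two-sided against the standard-normal critical values.  The
    optional Harvey-Leybourne-Newbold small-sample factor is off by default.
    """
    e1, e2 = _pair(errors_1, errors_2)
    n = e1.size
    if n < 10:
        raise ValueError("dm_test needs at least 10 observations")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if loss == "squared":
        d = e1**2 - e2**2
    elif loss == "absolute":
        d = np.abs(e1) - np.abs(e2)
    else:
        raise ValueError(f"unknown loss {loss!r}")

    dbar = d.mean()
    dc = d - dbar
    # rectangular HAC estimator of the long-run variance of dbar
    gamma0 = float(dc @ dc) / n
    lrv = gamma0
    for k in range(1, horizon):
        lrv += 2.0 * float(dc[:-k] @ dc[k:]) / n
    if lrv <= 0:
        stat = 0.0 if dbar == 0 else np.inf * np.sign(dbar)
    else:
        stat = dbar / np.sqrt(lrv / n)
        if harvey_correction:
            h = horizon
            stat *= np.sqrt((n + 1 - 2 * h + h * (h - 1) / n) / n)
    crit = (DM_CRITICAL_VALUES[0.90], DM_CRITICAL_VALUES[0.95], DM_CRITICAL_VALUES[0.99])
    a = abs(stat)
    return DmResult(
        statistic=float(stat),
        critical_values=crit,
        reject_90=bool(a > crit[0]),
        reject_95=bool(a > crit[1]),
        reject_99=bool(a > crit[2]),
    )


def var_residuals(y, yhat) -> float:
    """Stability measure: squared sample standard deviation of residuals."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("var_residuals needs at least two points")
    r = yhat - y
    return float(r.std(ddof=1) ** 2)


def evaluation_report(y, yhat) -> dict:
    """All scalar metrics for one truth/forecast pair, JSON-friendly."""
    y, yhat = _pair(y, yhat)
    return {
        "n": int(y.size),
        "mape": mape(y, yhat),
        "r2": r_squared(y, yhat),
        "var": var_residuals(y, yhat),
    }
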