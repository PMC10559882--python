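"""ARFIMA(p, d, q) modelling: fractional differencing, CSS estimation,
rolling one-step forecasting, and particle-swarm order selection.

The fractional differencing operator (1-B)^d is applied as a truncated
binomial-weight convolution whose truncation is the full available history
(series here are short, so exactness wins over speed).  After differencing
at a fixed d, the ARMA(p, q) part is estimated by conditional sum of
squares; d itself is treated as a searched parameter alongside the integer
orders, mirroring the particle layout (p, d, q).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .pso import PsoConfig, PsoResult, pso_optimize


class ArfimaFitError(RuntimeError):
    """Estimation failed to converge; carries optimizer diagnostics."""


def fracdiff_weights(d: float, K: int) -> np.ndarray:
    """Binomial weights c_0..c_K of (1-B)^d: c_0=1, c_k = c_{k-1}(k-1-d)/k."""
    if K < 0:
        raise ValueError("K must be >= 0")
    c = np.empty(K + 1)
    c[0] = 1.0
    for k in range(1, K + 1):
        c[k] = c[k - 1] * (k - 1 - d) / k
    return c


def _is_nonneg_integer(d: float) -> bool:
    return d >= 0 and abs(d - round(d)) < 1e-12


def frac_difference(series, d: float) -> np.ndarray:
    """Apply (1-B)^d with full-history truncation.

    For non-negative integer d the first d points (undefined under exact
    differencing) are dropped; for fractional d the full length is kept and
    the filter is truncated at the series start.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    if d == 0.0:
        return x.copy()
    c = fracdiff_weights(d, x.size - 1)
    w = signal.lfilter(c, [1.0], x)
    if _is_nonneg_integer(d):
        return w[int(round(d)):]
    return w


def frac_integrate(series, d: float, history=None) -> np.ndarray:
    """Exact inverse of :func:`frac_difference` given the same history.

    ``history`` supplies the original leading values dropped for integer d
    (or earlier sample values in rolling use); the reconstruction solves
    x_t = w_t - sum_{k>=1} c_k x_{t-k} sequentially.
    """
    w = np.asarray(series, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    if d == 0.0:
        return w.copy()
    hist = np.asarray(history, dtype=float) if history is not None else np.empty(0)
    m = hist.size
    n = w.size
    c = fracdiff_weights(d, m + n - 1)
    x = np.empty(m + n)
    x[:m] = hist
    for t in range(n):
        j = m + t
        kmax = j  # lags available
        acc = w[t]
        if kmax > 0:
            acc -= c[1 : kmax + 1] @ x[j - 1 :: -1][:kmax]
        x[j] = acc
    return x[m:]


@dataclass
class ArfimaSpec:
    """Orders, fitted coefficients and provenance of one ARFIMA model."""

    p: int
    d: float
    q: int
    ar_coeffs: np.ndarray = field(default_factory=lambda: np.empty(0))
    ma_coeffs: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean: float = 0.0
    sigma2: float = np.nan
    css: float = np.nan

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("orders must be non-negative")
        if abs(self.d) >= 0.5 and not _is_nonneg_integer(self.d):
            raise ValueError("d must satisfy |d| < 0.5 or be a non-negative integer")
        self.ar_coeffs = np.asarray(self.ar_coeffs, dtype=float)
        self.ma_coeffs = np.asarray(self.ma_coeffs, dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "p": self.p, "d": self.d, "q": self.q,
                "ar_coeffs": self.ar_coeffs.tolist(),
                "ma_coeffs": self.ma_coeffs.tolist(),
                "mean": self.mean, "sigma2": self.sigma2, "css": self.css,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArfimaSpec":
        obj = json.loads(text)
        return cls(
            p=obj["p"], d=obj["d"], q=obj["q"],
            ar_coeffs=np.asarray(obj["ar_coeffs"]),
            ma_coeffs=np.asarray(obj["ma_coeffs"]),
            mean=obj["mean"], sigma2=obj["sigma2"], css=obj["css"],
        )


def _css_residuals(w_centered: np.ndarray, ar: np.ndarray, ma: np.ndarray) -> np.ndarray:
    """CSS residual recursion e_t = w_t - sum(phi w) - sum(theta e), zero-init."""
    b = np.r_[1.0, -ar]
    a = np.r_[1.0, ma]
    return signal.lfilter(b, a, w_centered)


def css_objective(w_centered: np.ndarray, p: int, q: int):
    """Return the conditional-sum-of-squares loss over packed (phi, theta)."""

    def loss(params: np.ndarray) -> float:
        ar, ma = params[:p], params[p:]
        # soft guard: wildly explosive candidates give huge losses anyway,
        # but an invertibility wall keeps the MA recursion from overflowing
        if q and np.min(np.abs(np.roots(np.r_[ma[::-1], 1.0]))) <= 1.001:
            return np.inf
        e = _css_residuals(w_centered, ar, ma)
        e = e[p:]
        s = float(e @ e)
        return s if np.isfinite(s) else np.inf

    return loss


def fit_arfima(train, p: int, d: float, q: int) -> ArfimaSpec:
    """Fractionally difference at d, then estimate ARMA(p, q) by CSS.

    The mean of the differenced series is removed before estimation and
    stored; a stationarity check on the fitted AR polynomial warns (does not
    raise) when roots fall inside the unit circle.
    """
    x = np.asarray(train, dtype=float)
    if x.size <= 10 * (p + q + 1):
        raise ValueError(f"train length {x.size} too short for orders ({p},{q})")
    w = frac_difference(x, d)
    mu = float(w.mean())
    wc = w - mu

    if p + q == 0:
        e = wc
        return ArfimaSpec(p=0, d=d, q=0, mean=mu,
                          sigma2=float(e @ e) / e.size, css=float(e @ e))

    loss = css_objective(wc, p, q)
    x0 = np.zeros(p + q)
    if p:
        # Yule-Walker style warm start for the AR block
        from statsmodels.regression.linear_model import yule_walker

        try:
            rho, _ = yule_walker(wc, order=p, method="mle")
            x0[:p] = rho
        except Exception:
            pass
    res = optimize.minimize(loss, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10})
    if not np.isfinite(res.fun):
        raise ArfimaFitError(f"CSS estimation failed: {res.message}")
    ar, ma = res.x[:p], res.x[p:]
    if p and np.min(np.abs(np.roots(np.r_[-ar[::-1], 1.0]))) <= 1.0:
        warnings.warn("fitted AR polynomial has roots inside the unit circle", stacklevel=2)
    e = _css_residuals(wc, ar, ma)[p:]
    return ArfimaSpec(p=p, d=d, q=q, ar_coeffs=ar, ma_coeffs=ma, mean=mu,
                      sigma2=float(e @ e) / e.size, css=float(res.fun))


def _one_step_differenced(model: ArfimaSpec, w: np.ndarray, e: np.ndarray) -> float:
    """One-step forecast of the next differenced value given w and residuals."""
    wc = w - model.mean
    acc = model.mean
    for i in range(model.p):
        if len(wc) > i:
            acc += model.ar_coeffs[i] * wc[-1 - i]
    for j in range(model.q):
        if len(e) > j:
            acc += model.ma_coeffs[j] * e[-1 - j]
    return float(acc)


def forecast_arfima(model: ArfimaSpec, history, h: int = 1) -> np.ndarray:
    """Iterated h-step forecasts: ARMA recursion in the differenced domain,
    then fractional re-integration back to data units against ``history``."""
    if h < 1:
        raise ValueError("horizon must be >= 1")
    x = np.asarray(history, dtype=float)
    n = x.size
    c = fracdiff_weights(model.d, n + h - 1) if model.d != 0.0 else None
    w = signal.lfilter(fracdiff_weights(model.d, n - 1), [1.0], x) if model.d != 0.0 else x.copy()
    e = _css_residuals(w - model.mean, model.ar_coeffs, model.ma_coeffs)

    xs = list(x)
    ws = list(w)
    es = list(e)
    out = np.empty(h)
    for step in range(h):
        w_next = _one_step_differenced(model, np.asarray(ws), np.asarray(es))
        # integrate: x_t = w_t - sum_{k>=1} c_k x_{t-k}
        if model.d == 0.0:
            x_next = w_next
        else:
            t = len(xs)
            past = np.asarray(xs[::-1])
            x_next = w_next - float(c[1 : t + 1] @ past)
        out[step] = x_next
        xs.append(x_next)
        ws.append(w_next)
        es.append(0.0)  # future shocks at their expectation
    return out


def rolling_one_step(model: ArfimaSpec, history, actuals) -> np.ndarray:
    """One-step rolling forecasts over ``actuals``: each forecast uses all
    true values before it (filter update, no refitting)."""
    hist = list(np.asarray(history, dtype=float))
    truth = np.asarray(actuals, dtype=float)
    out = np.empty(truth.size)
    for t in range(truth.size):
        out[t] = forecast_arfima(model, np.asarray(hist), h=1)[0]
        hist.append(truth[t])
    return out


DEFAULT_ORDER_BOUNDS = ((0, 5), (-0.49, 0.49), (0, 5))


def tune_arfima(
    train,
    val,
    bounds=DEFAULT_ORDER_BOUNDS,
    pso_config: PsoConfig | None = None,
    fitness: str = "mape",
) -> tuple[ArfimaSpec, PsoResult]:
    """Select (p, d, q) by particle swarm on validation one-step error.

    Fitness is the validation MAPE of rolling one-step forecasts (RMSE when
    a validation truth is exactly zero, where MAPE is undefined).  The
    white-noise order (0, 0, 0) is seeded into the swarm so the tuned model
    never validates worse than that baseline.  Returns the refitted best
    spec and the swarm result.
    """
    from .metrics import mape

    tr = np.asarray(train, dtype=float)
    va = np.asarray(val, dtype=float)
    if tr.size == 0 or va.size == 0:
        raise ValueError("train and validation segments must be non-empty")
    cfg = pso_config or PsoConfig(swarm_size=10, iterations=8)
    use_mape = fitness == "mape" and not np.any(va == 0.0)

    def objective(pos: np.ndarray) -> float:
        p, d, q = int(round(pos[0])), float(pos[1]), int(round(pos[2]))
        try:
            m = fit_arfima(tr, p, d, q)
            pred = rolling_one_step(m, tr, va)
        except (ArfimaFitError, ValueError):
            return np.inf
        if use_mape:
            return mape(va, pred)
        return float(np.sqrt(np.mean((va - pred) ** 2)))

    result = pso_optimize(
        objective,
        bounds=bounds,
        integer_mask=[True, False, True],
        config=cfg,
        initial_positions=[[0.0, 0.0, 0.0]],
    )
    if not np.isfinite(result.best_fitness):
        raise ArfimaFitError("no candidate order fitted successfully")
    p, d, q = int(result.best_position[0]), float(result.best_position[1]), int(result.best_position[2])
    return fit_arfima(tr, p, d, q), result
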