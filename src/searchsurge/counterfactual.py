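"""Automatic ARIMA baseline selection, fitting, and counterfactual forecasting.

The model for the d-times differenced series w_t is a regression-with-ARMA-
errors form:  w_t = mu + z_t,  phi(B) z_t = theta(B) e_t,  e_t ~ N(0, sigma2).
For d = 0 ``mu`` is the series mean ("with mean"); for d = 1 it is the drift.
Likelihood maximization is delegated to statsmodels; differencing choice
(sequential KPSS), stepwise AICc order search, the forecast recursion and its
psi-weight variance accumulation live here so the residual bootstrap in
:mod:`searchsurge.excess` shares exactly one recursion with the point
forecast.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import itertools
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .data_model import QuerySeries

__all__ = [
    "ArimaSpec",
    "ForecastResult",
    "FitError",
    "choose_differencing",
    "fit_arima",
    "select_order",
    "forecast",
    "psi_weights",
    "simulate_forecast_paths",
]

_KPSS_ALPHA_KEYS = {0.10: "10%", 0.05: "5%", 0.025: "2.5%", 0.01: "1%"}

# minimum distance between AR and MA roots before a mixed fit is declared
# redundant (common-factor pathology: the likelihood gain is spurious)
_ROOT_CANCEL_GAP = 0.1


class FitError(RuntimeError):
    """Raised when an ARIMA fit fails or is infeasible."""


@dataclasses.dataclass(frozen=True)
class ArimaSpec:
    """A fitted ARIMA(p,d,q)(+constant/drift) baseline model.

    Carries everything the forecast recursion needs: coefficients, the
    innovation variance, the in-sample residuals on the differenced scale,
    and the tail of the training series.
    """

    p: int
    d: int
    q: int
    drift: bool
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    intercept: float  # mean of the d-differenced series (0 when drift=False)
    sigma2: float
    aicc: float
    n_obs: int  # length of the differenced series the likelihood used
    resid: np.ndarray = dataclasses.field(repr=False, default=None)
    w_tail: np.ndarray = dataclasses.field(repr=False, default=None)  # last p of w
    resid_tail: np.ndarray = dataclasses.field(repr=False, default=None)  # last q e
    y_tail: np.ndarray = dataclasses.field(repr=False, default=None)  # last d of y
    log_transform: bool = False

    def __post_init__(self):
        ar = np.atleast_1d(np.asarray(self.ar_coeffs, dtype=float)) if self.p else np.empty(0)
        ma = np.atleast_1d(np.asarray(self.ma_coeffs, dtype=float)) if self.q else np.empty(0)
        object.__setattr__(self, "ar_coeffs", ar)
        object.__setattr__(self, "ma_coeffs", ma)
        if self.sigma2 < 0:
            raise FitError("sigma2 must be non-negative")
        # causal/invertible <=> all polynomial roots strictly outside |z| = 1
        if self.p and np.any(np.abs(np.roots(np.r_[-ar[::-1], 1.0])) <= 1.0):
            raise FitError("AR polynomial not causal (root inside unit circle)")
        if self.q and np.any(np.abs(np.roots(np.r_[ma[::-1], 1.0])) <= 1.0):
            raise FitError("MA polynomial not invertible")

    @property
    def orders(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def n_params(self) -> int:
        # variance counts as a parameter in AICc
        return self.p + self.q + int(self.drift) + 1

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "d": self.d,
            "q": self.q,
            "drift": self.drift,
            "ar_coeffs": [float(x) for x in self.ar_coeffs],
            "ma_coeffs": [float(x) for x in self.ma_coeffs],
            "intercept": float(self.intercept),
            "sigma2": float(self.sigma2),
            "aicc": float(self.aicc),
            "n_obs": int(self.n_obs),
            "log_transform": bool(self.log_transform),
        }


@dataclasses.dataclass(frozen=True)
class ForecastResult:
    """Counterfactual point forecasts with prediction intervals."""

    dates: tuple
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    se: np.ndarray = dataclasses.field(default=None, repr=False)

    def __post_init__(self):
        for name in ("mean", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (np.all(self.lower <= self.mean + 1e-12) and np.all(self.mean <= self.upper + 1e-12)):
            raise ValueError("require lower <= mean <= upper pointwise")

    def __len__(self) -> int:
        return len(self.mean)


def _values(series) -> np.ndarray:
    if isinstance(series, QuerySeries):
        return series.values
    return np.asarray(series, dtype=float)


# level-stationarity critical values (Kwiatkowski et al. table)
_KPSS_CRIT = {"10%": 0.347, "5%": 0.463, "2.5%": 0.574, "1%": 0.739}


def kpss_level_stat(y: np.ndarray) -> float:
    """KPSS level-stationarity statistic with an AR(1)-prewhitened
    long-run-variance estimate.

    Plain Bartlett-kernel KPSS badly over-rejects for persistent stationary
    series (it would difference a phi = 0.8 AR(1) 15-25% of the time).
    Prewhitening the demeaned series with an AR(1) filter, estimating the
    short-bandwidth Bartlett LRV of the filtered residuals, and recoloring by
    1/(1 - rho)^2 — with rho capped at 1 - 1/sqrt(T) so unit roots keep the
    statistic divergent — restores near-nominal size while retaining power.
    """
    y = np.asarray(y, dtype=float)
    T = len(y)
    e = y - y.mean()
    denom = np.dot(e[:-1], e[:-1])
    rho = np.dot(e[1:], e[:-1]) / denom if denom > 0 else 0.0
    bound = 1.0 - 1.0 / np.sqrt(T)
    rho = float(np.clip(rho, -bound, bound))
    v = e[1:] - rho * e[:-1]
    lag = int(4 * (T / 100.0) ** 0.25)
    nv = len(v)
    lrv_v = np.dot(v, v) / nv
    for k in range(1, lag + 1):
        w = 1.0 - k / (lag + 1.0)
        lrv_v += 2.0 * w * np.dot(v[k:], v[:-k]) / nv
    lrv = lrv_v / (1.0 - rho) ** 2
    if lrv <= 0:
        return np.inf
    s = np.cumsum(e)
    return float(np.sum(s**2) / (T**2 * lrv))


def choose_differencing(series, alpha: float = 0.05, max_d: int = 2) -> int:
    """Smallest d <= max_d at which KPSS fails to reject level stationarity.

    Successive tests at level ``alpha`` (one of the tabulated 10%/5%/2.5%/1%
    points).  A constant (zero-variance) series is stationary by construction
    and returns the current d.
    """
    if alpha not in _KPSS_ALPHA_KEYS:
        raise ValueError(f"alpha must be one of {sorted(_KPSS_ALPHA_KEYS)}")
    crit = _KPSS_CRIT[_KPSS_ALPHA_KEYS[alpha]]
    y = _values(series)
    for d in range(max_d + 1):
        w = np.diff(y, n=d)
        if len(w) < 20:
            raise FitError(f"series too short for KPSS after {d} differences")
        if np.ptp(w) == 0:
            return d
        if kpss_level_stat(w) < crit:
            return d
    return max_d


def fit_arima(series, p: int, d: int, q: int, drift: bool = True) -> ArimaSpec:
    """Fit ARIMA(p,d,q) by Gaussian MLE on the d-differenced series.

    ``drift`` includes the constant term: the series mean when d = 0, the
    drift of the differenced series when d = 1.  AICc uses the small-sample
    correction with n = length of the differenced series.
    """
    from statsmodels.tsa.arima.model import ARIMA

    y = _values(series)
    if np.any(~np.isfinite(y)):
        raise FitError("non-finite values in series")
    w = np.diff(y, n=d) if d else y.copy()
    n = len(w)
    if n <= p + q + int(drift) + 1:
        raise FitError(f"series too short (n={n}) for orders ({p},{d},{q})")
    if np.ptp(w) == 0 and (p or q):
        raise FitError("differenced series is constant; ARMA terms unidentifiable")

    if p == 0 and q == 0:
        # closed form: intercept = sample mean, sigma2 = ML residual variance
        mu = float(np.mean(w)) if drift else 0.0
        resid = w - mu
        sigma2 = float(np.mean(resid**2))
        k = int(drift) + 1
        if sigma2 <= 0:
            sigma2 = 1e-300
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        aicc = -2 * ll + 2 * k + (2 * k * (k + 1)) / max(n - k - 1, 1)
        return ArimaSpec(
            p, d, q, drift, np.empty(0), np.empty(0), mu, sigma2, aicc, n,
            resid=resid, w_tail=np.empty(0), resid_tail=np.empty(0),
            y_tail=y[len(y) - d:] if d else np.empty(0),
        )

    trend = "c" if drift else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(w, order=(p, 0, q), trend=trend)
        try:
            res = model.fit()
        except Exception as exc:  # statsmodels raises many flavours
            raise FitError(f"ARIMA({p},{d},{q}) fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"ARIMA({p},{d},{q}) fit did not converge")

    mu = float(res.params[0]) if drift else 0.0
    ar = np.asarray(res.arparams, dtype=float)
    ma = np.asarray(res.maparams, dtype=float)
    if p and q:
        # common-factor pathology: near-cancelling AR/MA roots mean the fit is
        # over-parameterized (its likelihood gain is spurious) — reject it so
        # order search cannot be lured into redundant models
        ar_roots = np.roots(np.r_[-ar[::-1], 1.0])
        ma_roots = np.roots(np.r_[ma[::-1], 1.0])
        gap = np.min(np.abs(ar_roots[:, None] - ma_roots[None, :]))
        if gap < _ROOT_CANCEL_GAP:
            raise FitError(
                f"ARIMA({p},{d},{q}): near-cancelling AR/MA roots (gap {gap:.4f})"
            )
    sigma2 = float(res.params[-1])
    k = p + q + int(drift) + 1
    aicc = float(res.aic) + (2 * k * (k + 1)) / max(n - k - 1, 1)
    resid = np.asarray(res.resid, dtype=float)
    z = w - mu
    return ArimaSpec(
        p, d, q, drift, ar, ma, mu, sigma2, aicc, n,
        resid=resid,
        w_tail=z[n - p:] if p else np.empty(0),
        resid_tail=resid[n - q:] if q else np.empty(0),
        y_tail=y[len(y) - d:] if d else np.empty(0),
    )


def _stepwise_neighbors(p, q, drift, max_p, max_q, allow_drift):
    for dp, dq in itertools.product((-1, 0, 1), repeat=2):
        if dp == dq == 0:
            continue
        np_, nq = p + dp, q + dq
        if 0 <= np_ <= max_p and 0 <= nq <= max_q:
            yield np_, nq, drift
    if allow_drift:
        yield p, q, not drift


def select_order(
    series,
    max_p: int = 5,
    max_q: int = 5,
    alpha: float = 0.05,
    d: int | None = None,
    max_d: int = 2,
    cache: dict | None = None,
) -> ArimaSpec:
    """Stepwise AICc order search in the style of Hyndman & Khandakar.

    d comes from successive KPSS tests (unless given).  From each of the
    standard starting models — (2,d,2), (0,d,0), (1,d,0), (0,d,1), plus
    (0,d,0) without the constant — a greedy walk repeatedly moves to the best
    AICc neighbor (p +/- 1, q +/- 1, joint moves, constant toggle) until no
    improvement; the best endpoint over all walks is returned (fits are
    cached and shared between walks).  AICc ties break on smaller p+q, then
    smaller q.

    ``cache`` (optional, keyed by (p, q, drift)) collects every fit made
    during the search and reuses entries; callers sharing a cache must keep
    d fixed.
    """
    y = _values(series)
    if d is None:
        d = choose_differencing(y, alpha=alpha, max_d=max_d)
    allow_drift = d <= 1
    if cache is None:
        cache = {}

    def get(p, q, drift):
        key = (p, q, drift)
        if key not in cache:
            try:
                cache[key] = fit_arima(y, p, d, q, drift=drift)
            except FitError:
                cache[key] = None
        return cache[key]

    def score(spec):
        if spec is None:
            return (np.inf, np.inf, np.inf)
        return (spec.aicc, spec.p + spec.q, spec.q)

    def walk(spec):
        # greedy hill-climb: move to the best improving neighbor until stuck
        while True:
            step = None
            for p, q, dr in _stepwise_neighbors(
                spec.p, spec.q, spec.drift, max_p, max_q, allow_drift
            ):
                cand = get(p, q, dr)
                if score(cand) < score(step if step is not None else spec):
                    step = cand
            if step is None:
                return spec
            spec = step

    starts = [(2, 2, allow_drift), (0, 0, allow_drift), (1, 0, allow_drift),
              (0, 1, allow_drift)]
    if allow_drift:
        starts.append((0, 0, False))
    best = None
    for p, q, dr in starts:
        if p > max_p or q > max_q:
            continue
        spec = get(p, q, dr)
        if spec is None:
            continue
        end = walk(spec)
        if score(end) < score(best):
            best = end
    if best is None:
        raise FitError("all candidate fits failed")
    return best


def _phi_star(spec: ArimaSpec) -> np.ndarray:
    """Coefficients of phi(B)(1-B)^d expanded, as phi*_1..phi*_{p+d}."""
    poly = np.array([1.0])
    if spec.p:
        poly = np.convolve(poly, np.r_[1.0, -spec.ar_coeffs])
    for _ in range(spec.d):
        poly = np.convolve(poly, [1.0, -1.0])
    return -poly[1:]  # y_t = sum phi*_i y_{t-i} + ...


def psi_weights(spec: ArimaSpec, horizon: int) -> np.ndarray:
    """psi_0..psi_{horizon-1} of theta(B) / (phi(B) (1-B)^d)."""
    phi = _phi_star(spec)
    theta = spec.ma_coeffs
    psi = np.zeros(horizon)
    if horizon == 0:
        return psi
    psi[0] = 1.0
    for j in range(1, horizon):
        val = theta[j - 1] if j - 1 < len(theta) else 0.0
        kmax = min(j, len(phi))
        for i in range(1, kmax + 1):
            val += phi[i - 1] * psi[j - i]
        psi[j] = val
    return psi


def _integrate(spec: ArimaSpec, wf: np.ndarray, horizon: int) -> np.ndarray:
    """d-fold integration of differenced-scale forecasts given the last d
    original-scale values."""
    tails = []
    y = np.asarray(spec.y_tail, float)
    cur = y
    for _ in range(spec.d):
        tails.append(cur[-1])
        cur = np.diff(cur)
    out = wf
    for base in reversed(tails):
        out = base + np.cumsum(out)
    return out


def forecast(
    spec: ArimaSpec,
    horizon: int,
    level: float = 0.95,
    dates: Sequence | None = None,
    last_values: Sequence[float] | None = None,
) -> ForecastResult:
    """h-step counterfactual forecast with Gaussian prediction intervals.

    mean: conditional-expectation recursion; interval: mean +/- z * s_h with
    s_h^2 = sigma2 * sum(psi_j^2, j < h).  ``last_values`` optionally
    overrides the training-series tail stored on ``spec`` (original scale;
    MA residual history still comes from the fit).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if last_values is not None:
        y = np.asarray(last_values, dtype=float)
        if len(y) < spec.p + spec.d:
            raise ValueError(f"need at least p+d={spec.p + spec.d} last values")
        w = np.diff(y, n=spec.d) if spec.d else y
        spec = dataclasses.replace(
            spec,
            w_tail=(w - spec.intercept)[len(w) - spec.p:] if spec.p else np.empty(0),
            y_tail=y[len(y) - spec.d:] if spec.d else np.empty(0),
        )
    mean = _integrate(spec, _forecast_mean_diff(spec, horizon), horizon) if spec.d else (
        spec.intercept + _arma_mean_recursion(spec, horizon)
    )
    psi = psi_weights(spec, horizon)
    se = np.sqrt(spec.sigma2 * np.cumsum(psi**2))
    z = sps.norm.ppf(0.5 + level / 2)
    if dates is None:
        dates = tuple(range(1, horizon + 1))
    else:
        dates = tuple(dates)
        if len(dates) != horizon:
            raise ValueError("dates length must equal horizon")
    return ForecastResult(dates, mean, mean - z * se, mean + z * se, level, se=se)


def _arma_mean_recursion(spec: ArimaSpec, horizon: int) -> np.ndarray:
    p, q = spec.p, spec.q
    z_hist = list(spec.w_tail) if p else []
    e_hist = list(spec.resid_tail) if q else []
    zf = np.empty(horizon)
    for h in range(horizon):
        val = 0.0
        for i in range(1, p + 1):
            val += spec.ar_coeffs[i - 1] * z_hist[-i]
        for j in range(1, q + 1):
            lag = j - h  # index into pre-forecast residuals
            if lag >= 1 and len(e_hist) >= lag:
                val += spec.ma_coeffs[j - 1] * e_hist[-lag]
        zf[h] = val
        if p:
            z_hist.append(val)
    return zf


def _forecast_mean_diff(spec: ArimaSpec, horizon: int) -> np.ndarray:
    return spec.intercept + _arma_mean_recursion(spec, horizon)


def simulate_forecast_paths(
    spec: ArimaSpec,
    horizon: int,
    n_paths: int,
    rng: np.random.Generator,
    shocks: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate replicate future paths through the fitted recursion.

    Shocks default to iid resamples (with replacement) of the centered
    in-sample residuals — the model-residual bootstrap.  Returns an array of
    shape (n_paths, horizon) on the original series scale.
    """
    p, q, d = spec.p, spec.q, spec.d
    if shocks is None:
        resid = np.asarray(spec.resid, dtype=float)
        resid = resid - resid.mean()
        if np.ptp(resid) == 0:
            shocks = np.zeros((n_paths, horizon))
        else:
            idx = rng.integers(0, len(resid), size=(n_paths, horizon))
            shocks = resid[idx]
    else:
        shocks = np.asarray(shocks, dtype=float)
        if shocks.shape != (n_paths, horizon):
            raise ValueError("shocks must have shape (n_paths, horizon)")

    Z = np.tile(spec.w_tail, (n_paths, 1)) if p else np.zeros((n_paths, 0))
    E = np.tile(spec.resid_tail, (n_paths, 1)) if q else np.zeros((n_paths, 0))
    wf = np.empty((n_paths, horizon))
    for h in range(horizon):
        val = shocks[:, h].copy()
        for i in range(1, p + 1):
            val += spec.ar_coeffs[i - 1] * Z[:, -i]
        for j in range(1, q + 1):
            val += spec.ma_coeffs[j - 1] * E[:, -j]
        wf[:, h] = spec.intercept + val
        if p:
            Z = np.column_stack([Z[:, 1:], val]) if p > 1 else val[:, None]
        if q:
            E = np.column_stack([E[:, 1:], shocks[:, h]]) if q > 1 else shocks[:, h][:, None]
    # integrate d times
    out = wf
    tails = []
    cur = np.asarray(spec.y_tail, float)
    for _ in range(d):
        tails.append(cur[-1])
        cur = np.diff(cur)
    for base in reversed(tails):
        out = base + np.cumsum(out, axis=1)
    return out
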