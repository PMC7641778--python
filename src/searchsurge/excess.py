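"""Observed-vs-expected excess statistics with bootstrap uncertainty.

The cumulative statistic is a ratio of sums, sum(observed) / sum(expected),
not a mean of daily ratios; percent excess = (ratio - 1) * 100.  Uncertainty
comes from a model-residual bootstrap: replicate counterfactual paths are
simulated through the fitted ARIMA recursion with resampled residuals and
percentile intervals are read off the replicate distribution.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np

from .counterfactual import ArimaSpec, ForecastResult, simulate_forecast_paths
from .counterfactual import forecast as _point_forecast
from .data_model import QuerySeries

__all__ = [
    "ExcessResult",
    "excess_ratios",
    "bootstrap_excess_ci",
    "significance_flags",
    "absolute_volume",
]

FLOOR_FRACTION = 1e-6  # expected paths floored at this fraction of baseline mean


@dataclasses.dataclass(frozen=True)
class ExcessResult:
    """Daily and cumulative observed/expected excess with bootstrap CIs.

    ``cumulative_percent`` is (cumulative_ratio - 1) * 100 exactly; CIs are
    pointwise percentile intervals on the same percent scale.
    """

    dates: tuple
    observed: np.ndarray
    expected: np.ndarray
    daily_ratio: np.ndarray
    cumulative_ratio: float
    cumulative_percent: float
    daily_ci: np.ndarray | None = None  # (horizon, 2) ratio scale
    cumulative_ci: tuple | None = None  # percent scale
    B: int | None = None
    level: float | None = None
    seed: int | None = None
    n_floored: int = 0

    @property
    def significant(self) -> bool | None:
        """CI excludes 0% excess (lower bound above zero)."""
        if self.cumulative_ci is None:
            return None
        return self.cumulative_ci[0] > 0.0

    def to_dict(self) -> dict:
        d = {
            "dates": [str(x) for x in self.dates],
            "observed": [float(x) for x in self.observed],
            "expected": [float(x) for x in self.expected],
            "daily_ratio": [float(x) for x in self.daily_ratio],
            "cumulative_ratio": float(self.cumulative_ratio),
            "cumulative_percent": float(self.cumulative_percent),
            "n_floored": int(self.n_floored),
            "ci_type": "pointwise percentile bootstrap",
        }
        if self.daily_ci is not None:
            d["daily_ci"] = [[float(a), float(b)] for a, b in self.daily_ci]
        if self.cumulative_ci is not None:
            d["cumulative_ci_percent"] = [float(x) for x in self.cumulative_ci]
            d["significant"] = bool(self.significant)
        if self.B is not None:
            d["B"] = int(self.B)
        if self.level is not None:
            d["level"] = float(self.level)
        if self.seed is not None:
            d["seed"] = int(self.seed)
        return d


def _observed_arrays(observed_post) -> tuple[tuple, np.ndarray]:
    if isinstance(observed_post, QuerySeries):
        return tuple(observed_post.dates), observed_post.values
    vals = np.asarray(observed_post, dtype=float)
    return tuple(range(len(vals))), vals


def _floor(expected: np.ndarray, baseline_mean: float) -> tuple[np.ndarray, int]:
    eps = FLOOR_FRACTION * abs(baseline_mean)
    if eps <= 0:
        eps = FLOOR_FRACTION
    floored = expected < eps
    if floored.any():
        expected = np.where(floored, eps, expected)
    return expected, int(np.sum(floored))


def excess_ratios(observed_post, forecast: ForecastResult,
                  baseline_mean: float | None = None) -> ExcessResult:
    """Point excess estimates: per-day o_t / e_t and cumulative sum-ratio."""
    dates, obs = _observed_arrays(observed_post)
    exp = np.asarray(forecast.mean, dtype=float)
    if len(obs) != len(exp):
        raise ValueError("observed and forecast lengths differ")
    if isinstance(observed_post, QuerySeries) and not all(
        a == b for a, b in zip(dates, forecast.dates)
    ):
        raise ValueError("observed and forecast cover different dates")
    if baseline_mean is None:
        baseline_mean = float(np.mean(exp))
    exp, n_floored = _floor(exp, baseline_mean)
    if np.sum(exp) <= 0:
        raise ValueError("non-positive expected total after flooring")
    daily = obs / exp
    cum = float(np.sum(obs) / np.sum(exp))
    return ExcessResult(
        dates, obs, exp, daily, cum, (cum - 1.0) * 100.0, n_floored=n_floored
    )


def bootstrap_excess_ci(
    spec: ArimaSpec,
    baseline_series,
    observed_post,
    forecast: ForecastResult | None = None,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> ExcessResult:
    """Excess estimates with model-residual bootstrap percentile CIs.

    Each of the B replicates simulates a counterfactual post-window path by
    pushing resampled (centered) fit residuals through the model recursion;
    the replicate statistic compares observed against the replicate expected
    path.  Deterministic under fixed ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    base_vals = (
        baseline_series.values
        if isinstance(baseline_series, QuerySeries)
        else np.asarray(baseline_series, dtype=float)
    )
    baseline_mean = float(np.mean(base_vals))
    if forecast is None:
        obs_dates, obs_vals = _observed_arrays(observed_post)
        forecast = _point_forecast(spec, len(obs_vals), level=level, dates=obs_dates)
    point = excess_ratios(observed_post, forecast, baseline_mean=baseline_mean)
    obs = point.observed
    horizon = len(obs)

    resid = np.asarray(spec.resid, dtype=float)
    if np.ptp(resid) == 0 or spec.sigma2 == 0:
        warnings.warn("degenerate residuals: bootstrap CI has zero width")
        daily_ci = np.column_stack([point.daily_ratio, point.daily_ratio])
        pct = point.cumulative_percent
        return dataclasses.replace(
            point, daily_ci=daily_ci, cumulative_ci=(pct, pct),
            B=B, level=level, seed=seed,
        )

    rng = np.random.default_rng(seed)
    paths = simulate_forecast_paths(spec, horizon, B, rng)  # (B, horizon)
    eps = FLOOR_FRACTION * abs(baseline_mean)
    n_floored = int(np.sum(paths < eps)) + point.n_floored
    paths = np.maximum(paths, eps)

    lo_q = 100 * (1 - level) / 2
    hi_q = 100 - lo_q
    rep_cum = np.sum(obs) / np.sum(paths, axis=1)
    rep_pct = (rep_cum - 1.0) * 100.0
    cum_ci = (
        float(np.percentile(rep_pct, lo_q)),
        float(np.percentile(rep_pct, hi_q)),
    )
    rep_daily = obs[None, :] / paths
    daily_ci = np.column_stack(
        [np.percentile(rep_daily, lo_q, axis=0), np.percentile(rep_daily, hi_q, axis=0)]
    )
    return dataclasses.replace(
        point, daily_ci=daily_ci, cumulative_ci=cum_ci,
        B=B, level=level, seed=seed, n_floored=n_floored,
    )


def significance_flags(results: Mapping[str, ExcessResult] | ExcessResult):
    """Significant iff the cumulative CI lower bound exceeds 0% excess."""
    if isinstance(results, ExcessResult):
        if results.cumulative_ci is None:
            raise ValueError("CIs not computed")
        return results.significant
    out = {}
    for key, res in results.items():
        if res.cumulative_ci is None:
            raise ValueError(f"CIs not computed for {key}")
        out[key] = res.significant
    return out


def absolute_volume(
    result: ExcessResult,
    total_volume: Mapping | np.ndarray,
    round_to: int | None = 0,
) -> dict:
    """Convert query fractions to absolute search counts.

    ``total_volume`` gives total searches/day over the post window, either a
    mapping date -> volume or an array aligned with the result's dates.
    counts = qf / 1e7 * volume; excess counts use observed minus expected.
    """
    if isinstance(total_volume, Mapping):
        try:
            vol = np.array([float(total_volume[d]) for d in result.dates])
        except KeyError as exc:
            raise ValueError(f"missing volume for day {exc.args[0]}") from exc
    else:
        vol = np.asarray(total_volume, dtype=float)
        if len(vol) != len(result.dates):
            raise ValueError("volume series does not cover the post window")
    obs_counts = result.observed / 1e7 * vol
    exp_counts = result.expected / 1e7 * vol
    excess_counts = obs_counts - exp_counts

    def _round(x):
        return float(np.round(x, round_to)) if round_to is not None else float(x)

    return {
        "daily_observed_counts": [_round(x) for x in obs_counts],
        "daily_expected_counts": [_round(x) for x in exp_counts],
        "daily_excess_counts": [_round(x) for x in excess_counts],
        "total_observed": _round(np.sum(obs_counts)),
        "total_expected": _round(np.sum(exp_counts)),
        "total_excess": _round(np.sum(excess_counts)),
    }
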