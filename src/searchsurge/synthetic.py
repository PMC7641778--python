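"""Synthetic state x topic panels of daily query-fraction series.

Every downstream stage is exercised against data with known ground truth:
an ARMA (optionally integrated) baseline around a mean level, a
multiplicative event surge decaying exponentially toward an elevated floor,
and covariate-driven topic preferences (topic share linear in vote share).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisWindow, CovariateTable, QuerySeries

__all__ = [
    "SyntheticConfig",
    "generate_baseline",
    "apply_event_effect",
    "event_multiplier",
    "mean_event_multiplier",
    "generate_panel",
]

_STATE_CODES = [
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL", "GA", "HI",
    "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME", "MD", "MA", "MI", "MN",
    "MS", "MO", "MT", "NE", "NV", "NH", "NJ", "NM", "NY", "NC", "ND", "OH",
    "OK", "OR", "PA", "RI", "SC", "SD", "TN", "TX", "UT", "VT", "VA", "WA",
    "WV", "WI", "WY",
]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full ground-truth parameterization of a synthetic panel."""

    n_geographies: int = 51
    topics: tuple = ("union", "training", "immunity", "militarization")
    start: dt.date = dt.date(2010, 1, 1)
    end: dt.date = dt.date(2020, 7, 5)
    event_date: dt.date = dt.date(2020, 5, 25)
    # baseline ARIMA-like dynamics
    ar_coeffs: tuple = (0.6,)
    ma_coeffs: tuple = ()
    d: int = 0
    innovation_sd: float = 0.3
    mean_level: float = 4.0  # expected per-geography TOTAL qf/day over topics
    geo_level_sigma: float = 0.0  # lognormal spread of per-geography levels
    # event effect
    effect_multiplier: float = 37.7
    decay_halflife: float = 10.0
    floor_multiplier: float = 5.0
    # covariate-driven topic preferences: share = intercept + slope * vote
    topic_intercepts: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "union": 0.10, "training": 0.55, "immunity": 0.20, "militarization": 0.15,
        }
    )
    topic_slopes: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "union": 0.45, "training": -0.43, "immunity": 0.0, "militarization": -0.02,
        }
    )
    vote_share_range: tuple = (0.25, 0.75)
    seed: int = 0

    def __post_init__(self):
        if not (self.effect_multiplier >= self.floor_multiplier >= 1.0):
            raise ValueError("require effect_multiplier >= floor_multiplier >= 1")
        if self.innovation_sd < 0:
            raise ValueError("innovation sd must be >= 0")
        if self.d not in (0, 1):
            raise ValueError("baseline d must be 0 or 1")
        if set(self.topics) - set(self.topic_intercepts) or set(self.topics) - set(self.topic_slopes):
            raise ValueError("intercept/slope required for every topic")
        si = sum(self.topic_intercepts[t] for t in self.topics)
        ss = sum(self.topic_slopes[t] for t in self.topics)
        if abs(si - 1.0) > 1e-9 or abs(ss) > 1e-9:
            raise ValueError("topic intercepts must sum to 1 and slopes to 0")
        lo, hi = self.vote_share_range
        for v in (lo, hi):
            for t in self.topics:
                s = self.topic_intercepts[t] + self.topic_slopes[t] * v
                if not (0.0 < s < 1.0):
                    raise ValueError(
                        f"infeasible share system: topic {t!r} share {s:.3f} at "
                        f"vote share {v}"
                    )
        object.__setattr__(self, "topics", tuple(self.topics))

    @property
    def window(self) -> AnalysisWindow:
        return AnalysisWindow(self.start, self.event_date, self.end)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "SyntheticConfig":
        cfg = dict(cfg)
        for key in ("start", "end", "event_date"):
            if key in cfg and isinstance(cfg[key], str):
                cfg[key] = dt.date.fromisoformat(cfg[key])
        for key in ("topics", "ar_coeffs", "ma_coeffs", "vote_share_range"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def _check_arma(ar: Sequence[float], ma: Sequence[float]) -> None:
    ar = np.atleast_1d(np.asarray(ar, float)) if len(ar) else np.empty(0)
    ma = np.atleast_1d(np.asarray(ma, float)) if len(ma) else np.empty(0)
    if ar.size and np.any(np.abs(np.roots(np.r_[-ar[::-1], 1.0])) <= 1):
        raise ValueError("AR coefficients are not causal")
    if ma.size and np.any(np.abs(np.roots(np.r_[ma[::-1], 1.0])) <= 1):
        raise ValueError("MA coefficients are not invertible")


def generate_baseline(
    geography: str,
    topic: str,
    start: dt.date,
    end: dt.date,
    mean_level: float,
    ar_coeffs: Sequence[float] = (),
    ma_coeffs: Sequence[float] = (),
    d: int = 0,
    innovation_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
    burn: int = 200,
) -> tuple[QuerySeries, float]:
    """Sample a daily ARMA (d-integrated) path around ``mean_level``.

    Negative values from Gaussian noise are clipped at 0; the clip rate
    (fraction of days clipped) is returned alongside the series.
    """
    if start >= end:
        raise ValueError("start must precede end")
    _check_arma(ar_coeffs, ma_coeffs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = (end - start).days + 1
    ar = np.asarray(ar_coeffs, float)
    ma = np.asarray(ma_coeffs, float)
    p, q = len(ar), len(ma)
    total = n + burn
    e = rng.normal(0.0, innovation_sd, size=total) if innovation_sd > 0 else np.zeros(total)
    z = np.zeros(total)
    for t in range(total):
        val = e[t]
        for i in range(1, p + 1):
            if t - i >= 0:
                val += ar[i - 1] * z[t - i]
        for j in range(1, q + 1):
            if t - j >= 0:
                val += ma[j - 1] * e[t - j]
        z[t] = val
    z = z[burn:]
    if d == 1:
        z = np.cumsum(z)
    y = mean_level + z
    clipped = int(np.sum(y < 0))
    y = np.clip(y, 0.0, None)
    dates = [start + dt.timedelta(days=i) for i in range(n)]
    return QuerySeries(geography, topic, dates, y), clipped / n


def event_multiplier(
    t_days: np.ndarray, peak: float, halflife: float, floor: float
) -> np.ndarray:
    """m(t) = floor + (peak - floor) * 2^(-t / halflife), t in days >= 0."""
    t = np.asarray(t_days, dtype=float)
    return floor + (peak - floor) * np.power(2.0, -t / halflife)


def mean_event_multiplier(
    n_days: int, peak: float, halflife: float, floor: float
) -> float:
    """Closed-form mean of m(t) over t = 0..n_days-1 (geometric series)."""
    r = 2.0 ** (-1.0 / halflife)
    if r == 1.0:
        geo_sum = float(n_days)
    else:
        geo_sum = (1.0 - r**n_days) / (1.0 - r)
    return floor + (peak - floor) * geo_sum / n_days


def apply_event_effect(
    series: QuerySeries,
    event_date: dt.date,
    effect_multiplier: float,
    decay_halflife: float,
    floor_multiplier: float = 1.0,
) -> QuerySeries:
    """Multiply values on/after the event day by the decaying surge m(t)."""
    if not (series.start <= event_date <= series.end):
        raise ValueError(f"event_date {event_date} outside series span")
    values = series.values.copy()
    i0 = (event_date - series.start).days
    t = np.arange(len(values) - i0, dtype=float)
    values[i0:] *= event_multiplier(
        t, effect_multiplier, decay_halflife, floor_multiplier
    )
    return QuerySeries(series.geography, series.topic, series.dates, values)


def generate_panel(config: SyntheticConfig):
    """Generate the full panel: series, covariates, and ground truth.

    Returns ``(collection, covariates, truth)`` where ``truth`` records every
    injected parameter, each geography's vote share and expected topic
    shares, the actual counterfactual post-window path per series, and the
    closed-form mean post-window event multiplier.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_geographies <= len(_STATE_CODES):
        geos = _STATE_CODES[: cfg.n_geographies]
    else:
        geos = _STATE_CODES + [
            f"G{i:02d}" for i in range(cfg.n_geographies - len(_STATE_CODES))
        ]

    lo, hi = cfg.vote_share_range
    vote = rng.uniform(lo, hi, size=cfg.n_geographies)
    level_mult = (
        np.exp(rng.normal(0.0, cfg.geo_level_sigma, size=cfg.n_geographies))
        if cfg.geo_level_sigma > 0
        else np.ones(cfg.n_geographies)
    )
    window = cfg.window
    n_post = window.n_post

    series_out: list[QuerySeries] = []
    truth_series: dict[str, dict] = {}
    shares_truth: dict[str, dict] = {}
    clip_rates: dict[str, float] = {}
    for g, geo in enumerate(geos):
        shares = {
            t: cfg.topic_intercepts[t] + cfg.topic_slopes[t] * vote[g]
            for t in cfg.topics
        }
        shares_truth[geo] = shares
        for topic in cfg.topics:
            level = cfg.mean_level * level_mult[g] * shares[topic]
            sd = cfg.innovation_sd * level_mult[g] * shares[topic]
            base, clip = generate_baseline(
                geo, topic, cfg.start, cfg.end, level,
                cfg.ar_coeffs, cfg.ma_coeffs, cfg.d, sd, seed=rng,
            )
            clip_rates[f"{geo}/{topic}"] = clip
            bumped = apply_event_effect(
                base, cfg.event_date, cfg.effect_multiplier,
                cfg.decay_halflife, cfg.floor_multiplier,
            )
            series_out.append(bumped)
            i0 = (cfg.event_date - base.start).days
            cf = base.values[i0:]
            truth_series[f"{geo}/{topic}"] = {
                "counterfactual_post": [float(x) for x in cf],
                "observed_post": [float(x) for x in bumped.values[i0:]],
                "true_cumulative_ratio": float(
                    np.sum(bumped.values[i0:]) / np.sum(cf)
                ) if np.sum(cf) > 0 else None,
            }

    covariates = CovariateTable(
        pd.DataFrame(
            {
                "geography": geos,
                "vote_share_trump": vote,
                "winner": np.where(vote > 0.5, "Trump", "Clinton"),
            }
        )
    )
    truth = {
        "config": {
            "n_geographies": cfg.n_geographies,
            "topics": list(cfg.topics),
            "start": cfg.start.isoformat(),
            "end": cfg.end.isoformat(),
            "event_date": cfg.event_date.isoformat(),
            "ar_coeffs": list(cfg.ar_coeffs),
            "ma_coeffs": list(cfg.ma_coeffs),
            "d": cfg.d,
            "innovation_sd": cfg.innovation_sd,
            "mean_level": cfg.mean_level,
            "geo_level_sigma": cfg.geo_level_sigma,
            "effect_multiplier": cfg.effect_multiplier,
            "decay_halflife": cfg.decay_halflife,
            "floor_multiplier": cfg.floor_multiplier,
            "topic_intercepts": dict(cfg.topic_intercepts),
            "topic_slopes": dict(cfg.topic_slopes),
            "vote_share_range": list(cfg.vote_share_range),
            "seed": cfg.seed,
        },
        "vote_shares": {g: float(v) for g, v in zip(geos, vote)},
        "geo_level_multipliers": {g: float(m) for g, m in zip(geos, level_mult)},
        "expected_topic_shares": {
            g: {t: float(s) for t, s in d.items()} for g, d in shares_truth.items()
        },
        "mean_post_multiplier": mean_event_multiplier(
            n_post, cfg.effect_multiplier, cfg.decay_halflife, cfg.floor_multiplier
        ),
        "clip_rates": clip_rates,
        "series": truth_series,
    }
    return series_out, covariates, truth
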