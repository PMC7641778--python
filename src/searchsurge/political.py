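"""Association of topic shares with the 2016 vote-share covariate.

Unweighted OLS of a topic's share (fraction of the geography's all-topic
search volume) on the Trump vote-share fraction, with t-based slope CIs,
plus a categorical breakdown of leading topics by state winner.  The
per-10-point effect is 10 * slope: a 10-percentage-point vote-share increase
maps to 10*slope percentage points of topic share.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

from .data_model import CovariateTable
from .geo_topics import TopicShares

__all__ = ["VoteShareModel", "fit_vote_share_model", "winner_breakdown"]


@dataclasses.dataclass(frozen=True)
class VoteShareModel:
    """Fitted dose-response line of topic share on vote share."""

    topic: str
    slope: float
    intercept: float
    slope_ci: tuple
    per10_effect: float  # percentage points of share per 10 pp of vote share
    r2: float
    n: int
    level: float

    def __post_init__(self):
        lo, hi = self.slope_ci
        if not (lo <= self.slope <= hi):
            raise ValueError("CI must contain the slope point estimate")
        if abs(self.per10_effect - 10.0 * self.slope) > 1e-12:
            raise ValueError("per10_effect must equal 10 * slope")

    def to_dict(self) -> dict:
        return {
            "topic": self.topic,
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "slope_ci": [float(x) for x in self.slope_ci],
            "per10_effect": float(self.per10_effect),
            "r2": float(self.r2),
            "n": int(self.n),
            "level": float(self.level),
        }


def _aligned(shares: TopicShares, covariates: CovariateTable, topic: str):
    cov = covariates.frame.set_index("geography")
    common = [g for g in shares.frame.index if g in cov.index]
    if len(common) < 3:
        raise ValueError("need >= 3 geographies with both share and vote share")
    y = shares.frame.loc[common, topic].to_numpy(dtype=float)
    x = cov.loc[common, "vote_share_trump"].to_numpy(dtype=float)
    return x, y, common


def fit_vote_share_model(
    shares: TopicShares,
    covariates: CovariateTable,
    topic: str,
    level: float = 0.95,
    weights: np.ndarray | None = None,
) -> VoteShareModel:
    """OLS of topic share on vote share; CI from the t slope standard error.

    ``weights`` (optional, e.g. total QF per geography) switches to weighted
    least squares; the default is the unweighted fit.
    """
    x, y, common = _aligned(shares, covariates, topic)
    n = len(x)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in vote share")
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    dof = n - 2
    sigma2 = np.sum(w * resid**2) / dof
    se = np.sqrt(sigma2 / sxx)
    tcrit = sps.t.ppf(0.5 + level / 2, dof)
    syy = np.sum(w * (y - ybar) ** 2)
    r2 = 0.0 if syy == 0 else 1.0 - np.sum(w * resid**2) / syy
    return VoteShareModel(
        topic=topic,
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=(float(slope - tcrit * se), float(slope + tcrit * se)),
        per10_effect=float(10.0 * slope),
        r2=float(r2),
        n=n,
        level=level,
    )


def fit_all_topics(
    shares: TopicShares, covariates: CovariateTable, level: float = 0.95
) -> dict:
    return {
        t: fit_vote_share_model(shares, covariates, t, level=level)
        for t in shares.frame.columns
    }


def winner_breakdown(shares: TopicShares, covariates: CovariateTable) -> dict:
    """Within each 2016-winner group, percent of geographies led by each topic.

    Geographies with tied leaders are excluded from the percentages and
    reported under ``ties``; geographies lacking covariates are skipped.
    """
    winners = covariates.winners()
    topics = list(shares.frame.columns)
    groups: dict[str, dict] = {}
    for winner in ("Trump", "Clinton"):
        geos = [
            g for g in shares.frame.index
            if winners.get(g) == winner and g in shares.leading
        ]
        if not geos:
            raise ValueError(f"empty winner group: {winner}")
        counts = {t: 0 for t in topics}
        for g in geos:
            counts[shares.leading[g]] += 1
        groups[winner] = {
            "n": len(geos),
            "percent_leading": {
                t: 100.0 * counts[t] / len(geos) for t in topics
            },
            "counts": counts,
        }
    groups["ties"] = {g: list(v) for g, v in shares.ties.items()}
    return groups
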