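"""State-level summaries of cumulative query fractions across topics.

Builds the geography x topic panel of cumulative post-window query fractions
and derives rankings with fold-vs-mean contrasts, within-state topic shares,
leading-topic tallies, a one-way random-effects intraclass correlation, and
bottom-k vs top-k group contrasts with bootstrap CIs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import AnalysisWindow, CovariateTable, QuerySeries

__all__ = [
    "StatePanel",
    "TopicShares",
    "cumulative_qf",
    "build_panel",
    "rank_states",
    "topic_shares",
    "leading_topic_tally",
    "icc",
    "icc_anova_oracle",
    "group_contrast",
]


@dataclasses.dataclass(frozen=True)
class StatePanel:
    """Geography x topic matrix of cumulative query fractions, plus covariates."""

    frame: pd.DataFrame  # index geography, columns topics, cells cumulative QF
    window: AnalysisWindow | None = None
    covariates: CovariateTable | None = None

    def __post_init__(self):
        df = pd.DataFrame(self.frame)
        if (df.to_numpy(dtype=float) < 0).any():
            raise ValueError("cumulative QF must be non-negative")
        if df.isna().any().any():
            raise ValueError("panel has missing cells")
        object.__setattr__(self, "frame", df.astype(float))

    @property
    def geographies(self) -> list:
        return list(self.frame.index)

    @property
    def topics(self) -> list:
        return list(self.frame.columns)


@dataclasses.dataclass(frozen=True)
class TopicShares:
    """Per-geography topic shares (rows sum to 1) and leading topics.

    ``leading`` maps geography -> topic for unique leaders; geographies with
    an exact tie for the lead appear in ``ties`` (all tied topics listed) and
    are excluded from single-winner tallies.
    """

    frame: pd.DataFrame
    leading: dict
    ties: dict

    def __post_init__(self):
        rowsums = self.frame.sum(axis=1).to_numpy()
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValueError("shares must sum to 1 per geography")


def cumulative_qf(series: QuerySeries, window: AnalysisWindow) -> float:
    """Sum of daily query fractions over the closed post window."""
    if window.event_date < series.start or window.post_end > series.end:
        raise ValueError(
            f"post window [{window.event_date}, {window.post_end}] not covered "
            f"by series span [{series.start}, {series.end}]"
        )
    post = series.subset(window.event_date, window.post_end)
    return float(np.sum(post.values))


def build_panel(
    collection: Iterable[QuerySeries],
    window: AnalysisWindow,
    covariates: CovariateTable | None = None,
) -> StatePanel:
    """Cumulative post-window QF per (geography, topic) as a StatePanel."""
    cells: dict[str, dict[str, float]] = {}
    for s in collection:
        cells.setdefault(s.geography, {})[s.topic] = cumulative_qf(s, window)
    df = pd.DataFrame.from_dict(cells, orient="index").sort_index()
    if df.isna().any().any():
        missing = [
            (g, t) for g in df.index for t in df.columns if pd.isna(df.loc[g, t])
        ]
        raise ValueError(f"incomplete panel; missing cells: {missing[:5]}")
    return StatePanel(df, window=window, covariates=covariates)


def rank_states(
    panel: StatePanel, topic: str, exclude_focal: bool = False
) -> pd.DataFrame:
    """Descending QF ranking for one topic with fold-vs-mean contrasts.

    fold = QF / mean(QF over the comparison set); for geographies below the
    mean, percent_below_mean = (1 - fold) * 100.  The comparison-set mean
    includes the focal geography by default; ``exclude_focal`` switches to a
    leave-one-out mean (both conventions in circulation).  Ties share the
    minimum rank.
    """
    if len(panel.geographies) < 2:
        raise ValueError("ranking needs at least 2 geographies")
    qf = panel.frame[topic]
    n = len(qf)
    if exclude_focal:
        total = qf.sum()
        mean = (total - qf) / (n - 1)
    else:
        mean = pd.Series(qf.mean(), index=qf.index)
    if (mean <= 0).any():
        raise ValueError("zero comparison-set mean")
    fold = qf / mean
    out = pd.DataFrame(
        {
            "qf": qf,
            "fold_vs_mean": fold,
            "percent_below_mean": np.where(fold < 1, (1 - fold) * 100.0, np.nan),
            "rank": qf.rank(method="min", ascending=False).astype(int),
        }
    ).sort_values(["rank", "qf"], ascending=[True, False])
    out.index.name = "geography"
    return out


def topic_shares(panel: StatePanel) -> TopicShares:
    """Normalize each geography's row to shares of its all-topic total."""
    totals = panel.frame.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"all-zero topic row for geography {bad}")
    shares = panel.frame.div(totals, axis=0)
    leading: dict[str, str] = {}
    ties: dict[str, list] = {}
    for geo, row in shares.iterrows():
        top = row.max()
        leaders = [t for t in shares.columns if row[t] == top]
        if len(leaders) == 1:
            leading[geo] = leaders[0]
        else:
            ties[geo] = leaders
    return TopicShares(shares, leading, ties)


def leading_topic_tally(shares: TopicShares) -> dict:
    """Count geographies led by each topic; mean leading share per topic.

    Tied geographies are reported separately and excluded from the counts.
    """
    topics = list(shares.frame.columns)
    counts = {t: 0 for t in topics}
    lead_shares: dict[str, list] = {t: [] for t in topics}
    for geo, topic in shares.leading.items():
        counts[topic] += 1
        lead_shares[topic].append(float(shares.frame.loc[geo, topic]))
    return {
        "counts": counts,
        "mean_leading_share": {
            t: (float(np.mean(v)) if v else None) for t, v in lead_shares.items()
        },
        "ties": {g: list(v) for g, v in shares.ties.items()},
        "n_tied": len(shares.ties),
    }


def _rank_normalize(mat: np.ndarray) -> np.ndarray:
    # within-topic ranks scaled to (0, 1]; robust to the heavy right skew of QFs
    df = pd.DataFrame(mat)
    return df.rank(axis=0, method="average").to_numpy() / mat.shape[0]


def icc(panel: StatePanel, rank_normalize: bool = True) -> float:
    """One-way random-effects ICC(1): geography grouping, topics as repeats.

    ICC = (MS_between - MS_within) / (MS_between + (k-1) * MS_within).
    """
    mat = panel.frame.to_numpy(dtype=float)
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 geographies and >= 2 topics")
    if rank_normalize:
        mat = _rank_normalize(mat)
    if np.ptp(mat) == 0:
        raise ValueError("zero total variance")
    row_means = mat.mean(axis=1)
    grand = mat.mean()
    ms_between = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_within = np.sum((mat - row_means[:, None]) ** 2) / (n * (k - 1))
    return float((ms_between - ms_within) / (ms_between + (k - 1) * ms_within))


def icc_anova_oracle(mat: np.ndarray) -> float:
    """Brute-force one-way ANOVA ICC(1) from raw sums of squares.

    Independent of :func:`icc`: builds the full between/within decomposition
    from scratch for verification.
    """
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = mat.sum() / mat.size
    ss_total = sum((mat[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_between = sum(k * (mat[i].sum() / k - grand) ** 2 for i in range(n))
    ss_within = ss_total - ss_between
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    return (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)


def group_contrast(
    panel: StatePanel,
    k: int = 5,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Bottom-k vs top-k contrast of mean-over-topics QF, with bootstrap CI.

    contrast = (1 - mean_bottom / mean_top) * 100, i.e. how much lower the
    bottom group is.  The CI resamples geographies within each group.
    """
    means = panel.frame.mean(axis=1).sort_values()
    n = len(means)
    if 2 * k > n:
        raise ValueError(f"k={k} too large for {n} geographies")
    bottom = means.iloc[:k].to_numpy()
    top = means.iloc[-k:].to_numpy()
    if top.mean() <= 0:
        raise ValueError("top-group mean must be positive")
    point = (1.0 - bottom.mean() / top.mean()) * 100.0

    rng = np.random.default_rng(seed)
    idx_b = rng.integers(0, k, size=(B, k))
    idx_t = rng.integers(0, k, size=(B, k))
    mb = bottom[idx_b].mean(axis=1)
    mt = top[idx_t].mean(axis=1)
    ok = mt > 0
    reps = (1.0 - mb[ok] / mt[ok]) * 100.0
    lo_q = 100 * (1 - level) / 2
    return {
        "bottom_geographies": list(means.index[:k]),
        "top_geographies": list(means.index[-k:]),
        "mean_bottom": float(bottom.mean()),
        "mean_top": float(top.mean()),
        "percent_lower": float(point),
        "ci": [float(np.percentile(reps, lo_q)), float(np.percentile(reps, 100 - lo_q))],
        "B": B,
        "level": level,
        "seed": seed,
    }
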