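"""Monthly visit indicators, episode-of-care segmentation, and service-use
descriptives.

An episode of care (EoC) is a chronological cluster of at least three
visits, separated from neighbouring clusters by at least six months (180
days) with no visits. Clusters below the visit minimum are retained as
non-episode contacts so scattered pre- and post-episode visits remain
reportable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import month_edges

__all__ = [
    "Cluster",
    "EpisodePartition",
    "ServiceUseSummary",
    "month_indicators",
    "trajectory_matrix",
    "segment_episodes",
    "summarize_service_use",
    "summarize_cohort",
    "volume_shares",
]

DAYS_PER_MONTH = 365.25 / 12.0


def _as_day_offsets(dates, index_date=None) -> np.ndarray:
    """Coerce visit dates to integer day offsets (from index_date if given)."""
    arr = np.asarray(dates)
    if arr.size == 0:
        return np.empty(0, dtype=np.int64)
    if np.issubdtype(arr.dtype, np.number):
        off = arr.astype(float) if np.issubdtype(arr.dtype, np.floating) \
            else arr.astype(np.int64)
        if index_date is not None:
            off = off - index_date
        return off
    arr = arr.astype("datetime64[D]")
    anchor = np.datetime64(index_date, "D") if index_date is not None \
        else arr.min()
    return (arr - anchor).astype(np.int64)


def month_indicators(visit_dates, index_date=None, n_months: int = 48
                     ) -> np.ndarray:
    """Binary vector: entry m-1 is 1 iff at least one visit falls in month
    bin m (fixed-width 365.25/12-day bins from the index date)."""
    off = _as_day_offsets(visit_dates, index_date)
    edges = month_edges(n_months)
    if off.size and off.min() < 0:
        raise ValueError("visit precedes the index date")
    if off.size and off.max() >= edges[-1]:
        raise ValueError("visit beyond the observation window")
    out = np.zeros(n_months, dtype=np.int8)
    out[np.searchsorted(edges, off, side="right") - 1] = 1
    return out


def trajectory_matrix(visits: pd.DataFrame, index_dates: pd.Series,
                      n_months: int = 48) -> pd.DataFrame:
    """Stack per-child month indicators into an n x n_months 0/1 frame.

    ``index_dates`` (child_id -> date) defines both the cohort membership
    and the per-child month-1 anchor; visits of children absent from it are
    ignored.
    """
    by_child = visits.groupby("child_id")["visit_date"]
    rows = np.zeros((len(index_dates), n_months), dtype=np.int8)
    for i, (cid, idx_date) in enumerate(index_dates.items()):
        rows[i] = month_indicators(by_child.get_group(cid).to_numpy(),
                                   idx_date, n_months)
    return pd.DataFrame(rows, index=index_dates.index,
                        columns=[f"m{m:02d}" for m in range(1, n_months + 1)])


@dataclass(frozen=True)
class Cluster:
    first: float
    last: float
    n_visits: int
    is_episode: bool


@dataclass(frozen=True)
class EpisodePartition:
    clusters: tuple[Cluster, ...]

    @property
    def n_episodes(self) -> int:
        return sum(c.is_episode for c in self.clusters)

    @property
    def episodes(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.is_episode)


def segment_episodes(visit_dates, min_visits: int = 3, gap_days: int = 180
                     ) -> EpisodePartition:
    """Greedy chronological clustering: a new cluster starts whenever the
    gap since the previous visit is >= gap_days; clusters with >= min_visits
    visits are episodes of care."""
    off = np.sort(_as_day_offsets(visit_dates))
    if off.size == 0:
        return EpisodePartition(clusters=())
    breaks = np.nonzero(np.diff(off) >= gap_days)[0] + 1
    clusters = []
    for chunk in np.split(off, breaks):
        clusters.append(Cluster(first=float(chunk[0]), last=float(chunk[-1]),
                                n_visits=int(chunk.size),
                                is_episode=chunk.size >= min_visits))
    return EpisodePartition(clusters=tuple(clusters))


@dataclass
class ServiceUseSummary:
    n_episodes: int
    episode_category: str            # "0", "1" or "2+"
    total_visits: int
    duration_years: float            # (last visit - first visit) / 365.25
    over_two_years: bool
    pre_episode_visits: int
    inter_episode_gap_months: float | None
    per_episode: tuple[tuple[int, float], ...]  # (visits, duration months)


def summarize_service_use(partition: EpisodePartition, visit_dates
                          ) -> ServiceUseSummary:
    """Derive the utilization descriptives from an episode partition."""
    off = np.sort(_as_day_offsets(visit_dates))
    total = int(off.size)
    if total != sum(c.n_visits for c in partition.clusters):
        raise ValueError("partition does not match the visit dates")
    duration = float(off[-1] - off[0]) / 365.25 if total else 0.0
    episodes = partition.episodes
    pre = 0
    if episodes:
        first_ep_start = episodes[0].first
        pre = sum(c.n_visits for c in partition.clusters
                  if not c.is_episode and c.last < first_ep_start)
    gap = None
    if len(episodes) >= 2:
        gap = (episodes[1].first - episodes[0].last) / DAYS_PER_MONTH
    n_ep = len(episodes)
    category = "0" if n_ep == 0 else ("1" if n_ep == 1 else "2+")
    per_episode = tuple(
        (c.n_visits, (c.last - c.first) / DAYS_PER_MONTH) for c in episodes)
    return ServiceUseSummary(
        n_episodes=n_ep, episode_category=category, total_visits=total,
        duration_years=duration, over_two_years=duration > 2.0,
        pre_episode_visits=pre, inter_episode_gap_months=gap,
        per_episode=per_episode)


def summarize_cohort(visits: pd.DataFrame, index_dates: pd.Series,
                     min_visits: int = 3, gap_days: int = 180
                     ) -> pd.DataFrame:
    """Per-child service-use summary table for a whole cohort."""
    by_child = visits.groupby("child_id")["visit_date"]
    records = []
    for cid in index_dates.index:
        dates = by_child.get_group(cid).to_numpy()
        s = summarize_service_use(
            segment_episodes(dates, min_visits, gap_days), dates)
        records.append({
            "child_id": cid, "n_episodes": s.n_episodes,
            "episode_category": s.episode_category,
            "total_visits": s.total_visits,
            "duration_years": s.duration_years,
            "over_two_years": s.over_two_years,
            "pre_episode_visits": s.pre_episode_visits,
            "inter_episode_gap_months": s.inter_episode_gap_months,
        })
    return pd.DataFrame(records).set_index("child_id")


def volume_shares(summaries: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-class share (%) of all visits: class visit totals over the grand
    total; shares sum to 100."""
    totals = summaries["total_visits"].groupby(labels).sum()
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no visits: volume shares undefined")
    return totals / grand * 100.0
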