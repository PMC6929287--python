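"""Inclusion/exclusion rules that turn raw visit and child tables into the
analysis cohort, with an ordered attrition log.

Rules, applied in order after de-duplication:

1. restrict to face-to-face visits (phone and indirect contacts dropped);
2. index-visit rule — the earliest face-to-face visit inside the intake
   window with no face-to-face visit in the preceding 18 months (548 days);
   children without a qualifying index are removed;
3. remove children younger than 5 at the index visit;
4. remove children older than 13 at the index visit (retained: 5 <= age < 14);
5. remove children flagged for a pervasive developmental disorder /
   developmental disability program;
6. remove children with a complete prior episode of care (>= 3 visits,
   180-day gap rule) ending within 548 days before the intake-window start.

Rule 6 is anchored at the window start rather than the index date: rule 2
already guarantees a visit-free 548-day window before the index, so an
episode ending inside that span cannot exist; the recent-prior-episode
exclusion is only non-vacuous for episodes completed just before the study
window opens.

Retained children's visit streams are truncated to the 48 months following
their index visit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import month_edges
from .trajectories import segment_episodes

__all__ = ["CohortResult", "identify_index_visit", "apply_filters"]

LOOKBACK_DAYS = 548  # 18 months = round(365.25 * 1.5)


@dataclass
class CohortResult:
    """Filtered cohort: per-child index dates, truncated visits, attrition."""

    index_dates: pd.Series          # child_id -> index date
    visits: pd.DataFrame            # truncated to [index, index + 48 months)
    children: pd.DataFrame          # retained rows of the child table
    attrition: list[tuple[str, int]]
    n_input: int
    n_duplicates_dropped: int

    @property
    def retained_ids(self) -> set:
        return set(self.index_dates.index)

    def attrition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attrition, columns=["rule", "n_removed"])


def identify_index_visit(visit_dates, intake_window: tuple,
                         lookback_days: int = LOOKBACK_DAYS):
    """Earliest face-to-face visit inside the intake window whose preceding
    ``lookback_days`` contain no face-to-face visit; None if none qualifies.

    ``visit_dates`` must already be restricted to face-to-face contacts.
    """
    dates = np.sort(np.asarray(visit_dates, dtype="datetime64[D]"))
    if dates.size == 0:
        return None
    start = np.datetime64(intake_window[0], "D")
    end = np.datetime64(intake_window[1], "D")
    for i, d in enumerate(dates):
        if d < start or d > end:
            continue
        if i == 0 or (d - dates[i - 1]).astype(int) >= lookback_days:
            return d
    return None


def _age_at(dob, when) -> int:
    """Completed years between dob and a later date."""
    dob = pd.Timestamp(dob)
    when = pd.Timestamp(when)
    years = when.year - dob.year
    if (when.month, when.day) < (dob.month, dob.day):
        years -= 1
    return years


def apply_filters(children: pd.DataFrame, visits: pd.DataFrame,
                  intake_window: tuple, lookback_days: int = LOOKBACK_DAYS,
                  min_visits: int = 3, gap_days: int = 180,
                  n_months: int = 48) -> CohortResult:
    """Apply the participant-selection rules; see the module docstring."""
    n_input = children["child_id"].nunique()
    before = len(visits)
    visits = visits.drop_duplicates(
        subset=["child_id", "visit_date", "contact_mode"])
    n_dup = before - len(visits)

    f2f = visits[visits["contact_mode"] == "face_to_face"].copy()
    f2f["visit_date"] = pd.to_datetime(f2f["visit_date"])
    f2f = f2f.sort_values(["child_id", "visit_date"], kind="stable")
    window_start = np.datetime64(str(pd.Timestamp(intake_window[0]).date()))

    child_rows = children.set_index("child_id")
    by_child = {cid: g["visit_date"].to_numpy(dtype="datetime64[D]")
                for cid, g in f2f.groupby("child_id")}

    attrition: list[tuple[str, int]] = []
    alive = list(child_rows.index)

    # rules 1-2: face-to-face restriction + qualifying index visit
    index_dates = {}
    for cid in alive:
        d = identify_index_visit(by_child.get(cid, ()), intake_window,
                                 lookback_days)
        if d is not None:
            index_dates[cid] = d
    removed = [c for c in alive if c not in index_dates]
    attrition.append(("no_qualifying_index_visit", len(removed)))
    alive = [c for c in alive if c in index_dates]

    ages = {cid: _age_at(child_rows.loc[cid, "dob"], index_dates[cid])
            for cid in alive}
    under = [c for c in alive if ages[c] < 5]
    attrition.append(("age_under_5", len(under)))
    alive = [c for c in alive if ages[c] >= 5]

    over = [c for c in alive if ages[c] >= 14]
    attrition.append(("age_over_13", len(over)))
    alive = [c for c in alive if ages[c] < 14]

    pdd = [c for c in alive if bool(child_rows.loc[c, "pdd_flag"])]
    attrition.append(("pdd_dd_program", len(pdd)))
    alive = [c for c in alive if c not in set(pdd)]

    # rule 6: complete episode ending shortly before the intake window
    prior_eoc = []
    for cid in alive:
        pre = by_child[cid][by_child[cid] < index_dates[cid]]
        if pre.size < min_visits:
            continue
        part = segment_episodes(pre, min_visits=min_visits, gap_days=gap_days)
        for ep in part.episodes:
            end_day = pre.min() + np.timedelta64(int(ep.last), "D")
            if 0 < (window_start - end_day).astype(int) <= lookback_days:
                prior_eoc.append(cid)
                break
    attrition.append(("prior_episode_of_care", len(prior_eoc)))
    alive = [c for c in alive if c not in set(prior_eoc)]

    horizon_days = int(month_edges(n_months)[-1])
    idx = pd.Series(pd.to_datetime([index_dates[c] for c in alive]),
                    index=pd.Index(alive, name="child_id"),
                    name="index_date")
    f2f_alive = f2f[f2f["child_id"].isin(alive)].copy()
    if len(f2f_alive):
        idx_per_row = f2f_alive["child_id"].map(idx)
        offset = (f2f_alive["visit_date"] - idx_per_row).dt.days
        f2f_alive = f2f_alive[(offset >= 0) & (offset < horizon_days)]

    retained_children = children[children["child_id"].isin(alive)].copy()
    total_removed = sum(n for _, n in attrition)
    assert n_input == len(alive) + total_removed
    return CohortResult(index_dates=idx, visits=f2f_alive.reset_index(drop=True),
                        children=retained_children, attrition=attrition,
                        n_input=n_input, n_duplicates_dropped=n_dup)
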