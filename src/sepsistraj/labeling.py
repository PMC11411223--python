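"""Trajectory labeling from death times and vasopressor episodes.

Each enrolled patient is assigned one of three 48-h disease-progression
classes, judged over the window ``(t_enroll, t_enroll + 48 h]``:

* label 0, *rapid death* — died within 48 h of enrollment (death takes
  precedence over any weaning inside the window);
* label 2, *recovery* — liberated from vasopressor support within 48 h of
  enrollment and kept off vasopressors for at least 24 h after the last
  infusion stopped (the 24-h maintenance check is anchored at the
  liberation time and may extend past the window);
* label 1, *persistent ill* — everything else: ongoing support through the
  window (``ongoing_support``), or weaned but restarted within 24 h
  (``weaned_not_held``).

Raw infusion rows are fragmented (rate changes, chart artefacts), so they are
first merged into maximal episodes, joining gaps of at most ``merge_gap_hours``
(default 1 h) and dropping zero-rate records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation, DataError
from .synthetic import BundleSet

__all__ = ["VasoEpisode", "TrajectoryLabel", "merge_episodes",
           "assign_trajectory", "label_cohort"]

MAINTENANCE_HOURS = 24.0
DEFAULT_MERGE_GAP_HOURS = 1.0


@dataclass(frozen=True)
class VasoEpisode:
    start_ts: float
    end_ts: float
    drugs: frozenset[str]


@dataclass(frozen=True)
class TrajectoryLabel:
    value: int  # 0 rapid death, 1 persistent ill, 2 recovery
    basis: str  # death_in_window | weaned_and_held | ongoing_support | weaned_not_held
    t_off: float | None = None  # liberation time when weaning occurred


def merge_episodes(infusions: pd.DataFrame,
                   merge_gap_hours: float = DEFAULT_MERGE_GAP_HOURS
                   ) -> list[VasoEpisode]:
    """Union of positive-rate infusion intervals, merging gaps ≤ the tolerance."""
    if len(infusions) == 0:
        return []
    df = infusions[infusions["rate_value"] > 0]
    if len(df) == 0:
        return []
    if (df["start_hours"] >= df["end_hours"]).any():
        raise DataError("infusion interval with start >= end")
    df = df.sort_values(["start_hours", "end_hours"], kind="stable")
    episodes: list[VasoEpisode] = []
    cur_s = cur_e = None
    cur_drugs: set[str] = set()
    for s, e, d in zip(df["start_hours"], df["end_hours"], df["drug_name"]):
        if cur_s is None:
            cur_s, cur_e, cur_drugs = s, e, {d}
        elif s - cur_e <= merge_gap_hours:
            cur_e = max(cur_e, e)
            cur_drugs.add(d)
        else:
            episodes.append(VasoEpisode(cur_s, cur_e, frozenset(cur_drugs)))
            cur_s, cur_e, cur_drugs = s, e, {d}
    episodes.append(VasoEpisode(cur_s, cur_e, frozenset(cur_drugs)))
    return episodes


def assign_trajectory(t_enroll: float, death_time: float | None,
                      episodes: list[VasoEpisode],
                      window_hours: float = 48.0) -> TrajectoryLabel:
    """Classify one enrolled patient; see module docstring for the rules."""
    w_end = t_enroll + window_hours
    if death_time is not None and death_time <= w_end:
        return TrajectoryLabel(0, "death_in_window")
    overlapping = [ep for ep in episodes
                   if ep.start_ts <= w_end and ep.end_ts > t_enroll]
    if not overlapping:
        # no support after enrollment at all: liberated at enrollment
        return TrajectoryLabel(2, "weaned_and_held", t_off=t_enroll)
    # every in-window liberation must hold for 24 h; a restart within 24 h
    # of ANY liberation is a failed wean, even if a later wean holds
    liberations = sorted(ep.end_ts for ep in overlapping
                         if ep.end_ts <= w_end)
    failed = next(
        (e for e in liberations
         if any(e < ep.start_ts <= e + MAINTENANCE_HOURS
                for ep in episodes)), None)
    if any(ep.end_ts > w_end for ep in overlapping):
        # support still running at the end of the window
        if failed is not None:
            return TrajectoryLabel(1, "weaned_not_held", t_off=failed)
        return TrajectoryLabel(1, "ongoing_support")
    if failed is not None:
        return TrajectoryLabel(1, "weaned_not_held", t_off=failed)
    return TrajectoryLabel(2, "weaned_and_held", t_off=liberations[-1])


def label_cohort(cohort: pd.DataFrame, bundles: BundleSet,
                 merge_gap_hours: float = DEFAULT_MERGE_GAP_HOURS
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every eligible cohort row; returns (labeled cohort, summary).

    The summary table reports per-class counts and proportions over the
    eligible cohort.
    """
    out = cohort.copy()
    out["trajectory"] = np.nan
    out["basis"] = ""
    out["t_off"] = np.nan
    for i in out.index[~out["excluded"]]:
        pid = out.at[i, "patient_id"]
        try:
            b = bundles.bundle(pid, tables=("infusions",))
        except DataError as err:
            raise DataError(f"no event bundle for eligible patient {pid}") \
                from err
        if np.isnan(out.at[i, "t_enroll"]):
            raise ContractViolation(
                f"eligible patient {pid} has no enrollment time")
        episodes = merge_episodes(b.infusions, merge_gap_hours)
        lab = assign_trajectory(float(out.at[i, "t_enroll"]), b.death_time,
                                episodes)
        out.at[i, "trajectory"] = lab.value
        out.at[i, "basis"] = lab.basis
        out.at[i, "t_off"] = np.nan if lab.t_off is None else lab.t_off
    eligible = out[~out["excluded"]]
    counts = (eligible["trajectory"].astype("Int64")
              .value_counts().reindex([0, 1, 2], fill_value=0))
    n = int(counts.sum())
    summary = pd.DataFrame({
        "trajectory": [0, 1, 2],
        "name": ["rapid_death", "persistent_ill", "recovery"],
        "count": counts.to_numpy(dtype=int),
        "proportion": (counts / n).to_numpy(dtype=float) if n else
        np.zeros(3),
    })
    return out, summary
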