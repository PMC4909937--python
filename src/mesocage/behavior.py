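"""Behavioral analytics over cage event logs and the session table.

Per-mouse head-fixing and tube-entry rates, cohort mean±SD summaries,
inter-fixation intervals (with the trial-length comparison), and diurnal
6-hour binning of activity.  SD throughout is the sample (n-1) convention
and cohort rates are means of per-mouse rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .controller import EventLog

__all__ = [
    "MouseSummary",
    "CohortSummary",
    "round1",
    "summarize_mouse",
    "summarize_cohort",
    "log_to_counts",
    "interfix_intervals",
    "diurnal_bins",
]


def round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (display convention)."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class MouseSummary:
    """Per-mouse totals and daily rates (rates at full precision)."""

    animal_id: str
    entries: int
    head_fixes: int
    days_tested: float
    entries_per_day: float
    fixes_per_day: float

    @property
    def entries_per_day_1dp(self) -> float:
        return round1(self.entries_per_day)

    @property
    def fixes_per_day_1dp(self) -> float:
        return round1(self.fixes_per_day)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level mean±SD of the per-mouse daily rates."""

    n_mice: int
    mean_fixes_per_day: float
    sd_fixes_per_day: float
    mean_entries_per_day: float
    sd_entries_per_day: float
    total_head_fixes: int
    total_entries: int


def summarize_mouse(row) -> MouseSummary:
    """Summarize one mouse from a table row (mapping-like).

    Expects ``animal_id``, ``entries``, ``head_fixes`` and ``days_tested``;
    rates are computed at full precision (1-decimal rounding is a display
    property).
    """
    days = float(row["days_tested"])
    if days <= 0:
        raise ZeroDivisionError("days_tested must be positive")
    entries = int(row["entries"])
    fixes = int(row["head_fixes"])
    if fixes > entries:
        raise ValueError("head_fixes cannot exceed entries")
    return MouseSummary(str(row["animal_id"]), entries, fixes, days,
                        entries / days, fixes / days)


def log_to_counts(log: EventLog) -> pd.DataFrame:
    """Per-mouse entry/head-fix totals and active days from an event log.

    A mouse's tested days are the calendar (light-cycle) days with any
    activity of that mouse.
    """
    rows = []
    for tag in log.tags:
        events = log.for_tag(tag)
        days = {int((e.t / 86400.0)) for e in events}
        rows.append({"animal_id": tag,
                     "entries": sum(e.kind == "entry" for e in events),
                     "head_fixes": sum(e.kind == "fix_start" for e in events),
                     "days_tested": max(1, len(days))})
    return pd.DataFrame(rows)


def summarize_cohort(rows: pd.DataFrame,
                     cage_filter=None) -> CohortSummary:
    """Mean±sample-SD of per-mouse daily rates over a cohort.

    ``cage_filter`` restricts to cage-name prefixes (e.g. the lab-trained
    cages ``("AB", "EL", "EP")``); raises if the selection is empty.
    """
    df = rows
    if cage_filter is not None:
        prefixes = tuple(cage_filter)
        df = df[df["animal_id"].astype(str).str.startswith(prefixes)]
        if df.empty:
            raise ValueError(f"no mice match cage filter {cage_filter}")
    if len(df) < 2:
        raise ValueError("need at least two mice for an SD")
    summaries = [summarize_mouse(r) for _, r in df.iterrows()]
    fixes = np.array([s.fixes_per_day for s in summaries])
    entries = np.array([s.entries_per_day for s in summaries])
    return CohortSummary(
        n_mice=len(summaries),
        mean_fixes_per_day=float(fixes.mean()),
        sd_fixes_per_day=float(fixes.std(ddof=1)),
        mean_entries_per_day=float(entries.mean()),
        sd_entries_per_day=float(entries.std(ddof=1)),
        total_head_fixes=int(sum(s.head_fixes for s in summaries)),
        total_entries=int(sum(s.entries for s in summaries)))


def interfix_intervals(log: EventLog, by_trial_length: bool = False,
                       equal_var: bool = True):
    """Per-mouse intervals between successive head-fixations.

    Returns a DataFrame (tag, interval_s, trial_duration_s of the earlier
    fix).  With ``by_trial_length=True`` also returns a two-sample t-test
    comparing intervals grouped by the preceding trial's duration
    (Student's equal-variance by default, Welch with
    ``equal_var=False``) as ``(df, groups, t, p)``.
    """
    rows = []
    for tag in log.tags:
        fixes = [(e.t, e.payload.get("trial_duration_s"))
                 for e in log.for_tag(tag) if e.kind == "fix_start"]
        if len(fixes) < 2:
            if fixes:
                warnings.warn(f"{tag}: fewer than two head-fixes, no intervals")
            continue
        for (t0, dur), (t1, _) in zip(fixes, fixes[1:]):
            rows.append({"tag": tag, "interval_s": t1 - t0,
                         "trial_duration_s": dur})
    df = pd.DataFrame(rows, columns=["tag", "interval_s", "trial_duration_s"])
    if not by_trial_length:
        return df
    groups = {dur: g["interval_s"].to_numpy()
              for dur, g in df.groupby("trial_duration_s")}
    if len(groups) != 2:
        return df, groups, np.nan, np.nan
    (a, b) = groups.values()
    if a.var() == 0 and b.var() == 0 and np.isclose(a.mean(), b.mean()):
        return df, groups, 0.0, 1.0   # identical samples: no evidence
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return df, groups, float(t), float(p)


def diurnal_bins(log: EventLog, bin_hours: int = 6,
                 lights_on_hour: float | None = None) -> pd.DataFrame:
    """Entry/fix counts per (mouse, day, bin-of-day) with night flags.

    Bins partition the 24 h day starting at lights-on; night bins are
    those falling in the dark half of the 12 h:12 h cycle.  Bin sizes must
    divide 24.  Counts conserve the total event count of the counted
    kinds.
    """
    if 24 % bin_hours != 0:
        raise ValueError("bin_hours must divide 24")
    lights_on = log.t0_hour if lights_on_hour is None else lights_on_hour
    n_bins = 24 // bin_hours
    counts: dict = {}
    for e in log.events:
        if e.kind not in ("entry", "fix_start"):
            continue
        hours_since_lights_on = e.t / 3600.0 + log.t0_hour - lights_on
        day = int(math.floor(hours_since_lights_on / 24.0))
        bin_idx = int((hours_since_lights_on - day * 24.0) // bin_hours)
        key = (e.tag, day, bin_idx)
        rec = counts.setdefault(key, {"entries": 0, "head_fixes": 0})
        rec["entries" if e.kind == "entry" else "head_fixes"] += 1
    rows = []
    for (tag, day, bin_idx), rec in sorted(counts.items()):
        start_h = bin_idx * bin_hours
        night = start_h >= 12.0  # dark phase is the 12 h after lights-off
        rows.append({"tag": tag, "day": day, "bin": bin_idx,
                     "bin_start_hour_after_lights_on": start_h,
                     "night": night, **rec})
    return pd.DataFrame(rows, columns=["tag", "day", "bin",
                                       "bin_start_hour_after_lights_on",
                                       "night", "entries", "head_fixes"])
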