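"""Time-to-onset of the adverse event and serious-outcome comparisons.

Time to onset is the calendar-day difference between the adverse-event
date (DEMO ``event_dt``) and the suspect drug's therapy start date (THER
``start_dt``).  FAERS dates are yyyymmdd strings and often partial, so the
analysis keeps only cases where both dates carry full year, month and day,
and drops events dated before the drug started.  Same-day onset counts as
0 days and is kept.  Summaries are the sample mean, the sample standard
deviation (n-1 denominator) and the cumulative proportion of onsets by
each day — the curve behind "x% of events within d days" statements.

The outcome comparison contrasts each serious-outcome code (death,
life-threatening, hospitalization, disability, congenital anomaly,
required intervention, other) between event and non-event cases within an
exposure group, with Pearson chi-square or Fisher's exact test per the
sparse-cell rule.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OUTCOME_SEVERITY
from .stats import choose_test, fisher_2x2, pearson_rxc

__all__ = [
    "Onset",
    "OnsetSummary",
    "onset_days",
    "onset_records",
    "onset_summary",
    "cumulative_curve",
    "outcome_comparison",
]


@dataclass(frozen=True)
class Onset:
    """Either a day count or an exclusion reason (never both)."""

    days: int | None
    reason: str | None = None  # partial_date | invalid_date | negative_interval

    @property
    def included(self) -> bool:
        return self.days is not None


def _parse_full_date(s: str) -> dt.date | None | str:
    """Full yyyymmdd -> date; returns the exclusion reason otherwise."""
    s = (s or "").strip()
    if len(s) != 8 or not s.isdigit():
        return "partial_date"
    try:
        return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return "invalid_date"


def onset_days(event_dt: str, start_dt: str) -> Onset:
    """Days from therapy start to event, or the reason for exclusion.

    Both dates must be full 8-digit yyyymmdd; an event strictly before the
    start is excluded as ``negative_interval``; same-day onset is 0.
    """
    ev = _parse_full_date(event_dt)
    st = _parse_full_date(start_dt)
    for parsed in (ev, st):
        if isinstance(parsed, str):
            return Onset(None, parsed)
    delta = (ev - st).days
    if delta < 0:
        return Onset(None, "negative_interval")
    return Onset(delta)


def onset_records(cohort: pd.DataFrame, events_only: bool = True) -> pd.DataFrame:
    """Per-case onset table with exclusion accounting.

    Returns one row per (event) case with columns ``caseid, exposure,
    event, days, reason``; ``days`` is NaN for excluded rows and
    ``included + sum(excluded by reason) == input rows``.
    """
    sub = cohort[cohort["event"]] if events_only else cohort
    rows = []
    for r in sub.itertuples(index=False):
        o = onset_days(r.event_dt, r.start_dt)
        rows.append(
            {
                "caseid": r.caseid,
                "exposure": r.exposure,
                "event": r.event,
                "days": o.days if o.included else np.nan,
                "reason": o.reason or "",
            }
        )
    return pd.DataFrame(rows, columns=["caseid", "exposure", "event", "days", "reason"])


@dataclass
class OnsetSummary:
    n: int
    mean: float | None
    sd: float | None  # sample SD (n-1); None when n < 2
    cumulative: pd.DataFrame  # columns: day, cum_prop


def cumulative_curve(days) -> pd.DataFrame:
    """Fraction of onsets occurring by each observed day (non-decreasing,
    reaching 1 at the maximum observed day)."""
    arr = np.sort(np.asarray(list(days), dtype=float))
    if arr.size == 0:
        return pd.DataFrame(columns=["day", "cum_prop"])
    uniq, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts) / arr.size
    return pd.DataFrame({"day": uniq.astype(int), "cum_prop": cum})


def onset_summary(days) -> OnsetSummary:
    """Mean, sample SD and cumulative-onset curve of a day sequence."""
    arr = np.asarray([d for d in days if d == d], dtype=float)
    n = arr.size
    return OnsetSummary(
        n=int(n),
        mean=float(arr.mean()) if n else None,
        sd=float(arr.std(ddof=1)) if n > 1 else None,
        cumulative=cumulative_curve(arr),
    )


def outcome_comparison(cohort: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-outcome event vs non-event contrast within one exposure group.

    Only cases that reported at least one outcome enter (the denominator
    is cases with outcome data, as in standard FAERS outcome tables).  For
    each code the 2x2 is (event cases with/without the outcome) x
    (non-event cases with/without); the test is Pearson chi-square, or
    Fisher's exact when any expected count is below 5.

    Returns a frame with one row per outcome code: counts, column
    percentages, test name and p-value.
    """
    sub = cohort[(cohort["exposure"] == group) & (cohort["outcome"] != "none")]
    ev = sub[sub["event"]]
    nev = sub[~sub["event"].astype(bool)]
    n_ev, n_nev = len(ev), len(nev)
    rows = []
    for code in OUTCOME_SEVERITY:
        a = int((ev["outcome"] == code).sum())
        c = int((nev["outcome"] == code).sum())
        b, d = n_ev - a, n_nev - c
        table = [[a, b], [c, d]]
        test = choose_test(table)
        if n_ev == 0 or n_nev == 0:
            test, p = "skipped", np.nan
        elif test == "fisher":
            p = fisher_2x2(a, b, c, d)
        else:
            p = pearson_rxc(table).p
        rows.append(
            {
                "outcome": code,
                "event_n": a,
                "event_pct": 100.0 * a / n_ev if n_ev else 0.0,
                "nonevent_n": c,
                "nonevent_pct": 100.0 * c / n_nev if n_nev else 0.0,
                "test": test,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
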