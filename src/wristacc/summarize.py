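"""Daily and weekly outcome aggregation with validity and compliance rules.

Bouts from one recording day are reduced to four accelerometry outcomes:
active time as a ratio of total recorded time, mean AC per active minute,
and the proportions of low / medium / high intensity activities.  Visit days
are dropped (they are incomplete and behaviourally atypical), days with too
little wear are flagged invalid, and weeks with fewer than 3 valid days are
flagged invalid and excluded from analysis.  Compliance is reported as the
percentage of missing days over total participant-days together with the
fraction of valid weeks.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .signal import ActivityBout, HIA, LIA, MIA, InputError

__all__ = [
    "DailySummary",
    "DailyPRO",
    "WeeklySummary",
    "ComplianceReport",
    "summarize_day",
    "exclude_visit_days",
    "summarize_week",
    "compliance",
    "MIN_VALID_DAYS",
    "MIN_WEAR_S",
]

#: weeks need at least this many valid days to count
MIN_VALID_DAYS = 3
#: a day needs at least this much recorded wear to be a valid day (1 h);
#: the threshold excludes charge-failure fragments
MIN_WEAR_S = 3600.0


@dataclass
class DailySummary:
    """Per-day accelerometry outcomes."""

    date: dt.date
    wear_time_s: float
    active_time_ratio: float
    mean_ac_per_active_minute: float | None
    prop_lia: float
    prop_mia: float
    prop_hia: float
    n_bouts: int
    valid: bool = True


@dataclass
class DailyPRO:
    """Daily patient-reported outcomes, each 0-100 or None when missing."""

    date: dt.date
    vas_pain_mm: float | None = None
    vas_activity_mm: float | None = None
    sane: float | None = None

    def __post_init__(self) -> None:
        for name in ("vas_pain_mm", "vas_activity_mm", "sane"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise InputError(f"{name}={v} outside [0, 100]")


@dataclass
class WeeklySummary:
    """Arithmetic means of daily variables over the valid days of one week."""

    week_label: str
    means: dict[str, float | None]
    n_valid_days: int
    valid: bool


@dataclass
class ComplianceReport:
    total_participant_days: int
    missing_days: float
    pct_missing: float
    n_weeks: int = 0
    n_valid_weeks: int = 0
    pct_valid_weeks: float = float("nan")


def summarize_day(
    bouts: Sequence[ActivityBout],
    wear_time_s: float,
    date: dt.date | None = None,
    *,
    rate: float = 50.0,
    time_weighted_proportions: bool = False,
    min_wear_s: float = MIN_WEAR_S,
) -> DailySummary:
    """Reduce one day's bouts to the four accelerometry outcome variables.

    ``active_time_ratio`` is total bout duration over recorded wear time;
    ``mean_ac_per_active_minute`` is total AC over active minutes (None when
    there are no bouts); intensity proportions are bout-count fractions per
    class by default (``time_weighted_proportions`` switches to
    duration-weighted fractions).
    """
    if wear_time_s <= 0:
        raise InputError(f"wear_time_s must be positive, got {wear_time_s}")
    durations = np.array([b.duration_s for b in bouts], dtype=float)
    total_active_s = float(durations.sum())
    if total_active_s > wear_time_s + 1e-9:
        raise InputError(
            f"total bout duration {total_active_s:.1f}s exceeds wear time "
            f"{wear_time_s:.1f}s"
        )
    if bouts:
        total_ac = float(sum(b.activity_count for b in bouts))
        mean_ac = total_ac / (total_active_s / 60.0)
        if time_weighted_proportions:
            weights = {
                cls: float(
                    sum(b.duration_s for b in bouts if b.intensity == cls)
                )
                / total_active_s
                for cls in (LIA, MIA, HIA)
            }
        else:
            weights = {
                cls: sum(1 for b in bouts if b.intensity == cls) / len(bouts)
                for cls in (LIA, MIA, HIA)
            }
    else:
        mean_ac = None
        weights = {LIA: 0.0, MIA: 0.0, HIA: 0.0}
    return DailySummary(
        date=date if date is not None else dt.date(1970, 1, 1),
        wear_time_s=wear_time_s,
        active_time_ratio=min(total_active_s / wear_time_s, 1.0),
        mean_ac_per_active_minute=mean_ac,
        prop_lia=weights[LIA],
        prop_mia=weights[MIA],
        prop_hia=weights[HIA],
        n_bouts=len(bouts),
        valid=wear_time_s >= min_wear_s,
    )


def exclude_visit_days(
    days: Sequence[DailySummary], visit_dates: Iterable[dt.date]
) -> list[DailySummary]:
    """Drop visit days (incomplete, behaviourally atypical); order kept."""
    visits = set(visit_dates)
    return [d for d in days if d.date not in visits]


_DAILY_VARIABLES = (
    "active_time_ratio",
    "mean_ac_per_active_minute",
    "prop_lia",
    "prop_mia",
    "prop_hia",
    "wear_time_s",
)


def summarize_week(
    days: Sequence[DailySummary],
    label: str,
    min_valid_days: int = MIN_VALID_DAYS,
    pros: Sequence[DailyPRO] = (),
) -> WeeklySummary:
    """Arithmetic means over the week's valid days; flagged, never dropped.

    A week with fewer than ``min_valid_days`` valid days is returned with
    ``valid=False`` so callers can report it before excluding it.  Missing
    daily PRO values are excluded pairwise from their own means.
    """
    valid_days = [d for d in days if d.valid]
    means: dict[str, float | None] = {}
    for var in _DAILY_VARIABLES:
        vals = [
            getattr(d, var)
            for d in valid_days
            if getattr(d, var) is not None
        ]
        means[var] = float(np.mean(vals)) if vals else None
    for var in ("vas_pain_mm", "vas_activity_mm", "sane"):
        vals = [getattr(p, var) for p in pros if getattr(p, var) is not None]
        means[var] = float(np.mean(vals)) if vals else None
    return WeeklySummary(
        week_label=label,
        means=means,
        n_valid_days=len(valid_days),
        valid=len(valid_days) >= min_valid_days,
    )


def compliance(
    days_expected: int,
    days_with_data: float,
    weeks: Sequence[WeeklySummary] = (),
) -> ComplianceReport:
    """Percentage of missing days and fraction of valid follow-up weeks."""
    if days_expected <= 0:
        raise InputError("days_expected must be positive")
    if not (0 <= days_with_data <= days_expected):
        raise InputError(
            "days_with_data must lie in [0, days_expected]"
        )
    missing = days_expected - days_with_data
    n_weeks = len(weeks)
    n_valid = sum(1 for w in weeks if w.valid)
    return ComplianceReport(
        total_participant_days=days_expected,
        missing_days=missing,
        pct_missing=100.0 * missing / days_expected,
        n_weeks=n_weeks,
        n_valid_weeks=n_valid,
        pct_valid_weeks=(100.0 * n_valid / n_weeks) if n_weeks else float("nan"),
    )
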