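"""Review scheduling: tier-dependent due windows and an ordered worklist.

The panel's winning review frequencies are every 1-2 days for red
(high-risk) patients, every 2-4 days for amber, and once every working
week — or sooner on referral — for green. Red and amber windows are
calendar days; the green deadline is the fifth working day after the
last review, with Monday-Friday as the default working week and a
configurable holiday list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

from .catalog import Tier
from .triage import TriageResult


class ScheduleError(ValueError):
    """Invalid scheduling input."""


@dataclass(frozen=True)
class ReviewPolicy:
    """Per-tier review intervals.

    ``red`` and ``amber`` are (min, max) calendar-day offsets from the
    last review; ``green_working_days`` is the number of working days
    allowed before a green patient falls due.
    """

    red: tuple[int, int] = (1, 2)
    amber: tuple[int, int] = (2, 4)
    green_working_days: int = 5
    working_days: frozenset[int] = frozenset({0, 1, 2, 3, 4})  # Mon..Fri
    holidays: frozenset[date] = frozenset()

    def __post_init__(self) -> None:
        for name in ("red", "amber"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ScheduleError(f"{name} interval must satisfy 0 < min <= max")
        if self.green_working_days <= 0:
            raise ScheduleError("green_working_days must be positive")
        if not self.working_days:
            raise ScheduleError("working-day set cannot be empty")

    def is_working_day(self, day: date) -> bool:
        return day.weekday() in self.working_days and day not in self.holidays


DEFAULT_REVIEW_POLICY = ReviewPolicy()


def add_working_days(start: date, n: int, policy: ReviewPolicy) -> date:
    """The n-th working day strictly after ``start``."""
    day = start
    remaining = n
    while remaining > 0:
        day += timedelta(days=1)
        if policy.is_working_day(day):
            remaining -= 1
    return day


def due_window(last_review: date, tier: Tier | str,
               policy: ReviewPolicy = DEFAULT_REVIEW_POLICY) -> tuple[date, date]:
    """The (earliest, latest) due dates for the next review."""
    tier = Tier(tier)
    if tier is Tier.UNASSIGNED:
        raise ScheduleError("cannot schedule an unassigned tier")
    if tier is Tier.GREEN:
        earliest = last_review + timedelta(days=1)
        latest = add_working_days(last_review, policy.green_working_days, policy)
        return earliest, max(earliest, latest)
    lo, hi = policy.red if tier is Tier.RED else policy.amber
    return last_review + timedelta(days=lo), last_review + timedelta(days=hi)


@dataclass(frozen=True)
class ReviewSchedule:
    patient_id: str
    tier: Tier
    last_review: date
    earliest: date
    latest: date
    referral: bool = False

    def __post_init__(self) -> None:
        if self.earliest > self.latest:
            raise ScheduleError("earliest due date after latest")

    @classmethod
    def for_patient(cls, patient_id: str, tier: Tier | str, last_review: date,
                    policy: ReviewPolicy = DEFAULT_REVIEW_POLICY
                    ) -> "ReviewSchedule":
        earliest, latest = due_window(last_review, tier, policy)
        return cls(patient_id=patient_id, tier=Tier(tier),
                   last_review=last_review, earliest=earliest, latest=latest)

    def overdue(self, on: date) -> bool:
        return on > self.latest

    def days_overdue(self, on: date) -> int:
        return max(0, (on - self.latest).days)


def mark_referral(schedule: ReviewSchedule, when: date) -> ReviewSchedule:
    """Pull the review forward for a referral received on ``when``.

    The latest due date never moves later: a referral after the current
    deadline only sets the flag.
    """
    if when < schedule.last_review:
        raise ScheduleError("referral date precedes the last review")
    latest = min(schedule.latest, when)
    return replace(schedule, referral=True, latest=latest,
                   earliest=min(schedule.earliest, latest))


_TIER_ORDER = {Tier.RED: 0, Tier.AMBER: 1, Tier.GREEN: 2, Tier.UNASSIGNED: 3}


def worklist(results: Sequence[TriageResult],
             schedules: Iterable[ReviewSchedule],
             today: date) -> list[ReviewSchedule]:
    """Order patients for review on ``today``.

    Strata: overdue first, then due today, then future; within each
    stratum red before amber before green, then days overdue
    (descending), then patient id. The output is a permutation of the
    input schedules; a triage result without a schedule is an error.
    """
    by_id: dict[str, ReviewSchedule] = {}
    for s in schedules:
        if s.patient_id in by_id:
            raise ScheduleError(f"duplicate schedule for patient {s.patient_id!r}")
        by_id[s.patient_id] = s
    missing = [r.patient_id for r in results if r.patient_id not in by_id]
    if missing:
        raise ScheduleError(f"missing schedule for patients: {missing}")

    def stratum(s: ReviewSchedule) -> int:
        if s.overdue(today):
            return 0
        if s.earliest <= today <= s.latest:
            return 1
        return 2

    ordered = sorted(
        by_id.values(),
        key=lambda s: (stratum(s), _TIER_ORDER[s.tier],
                       -s.days_overdue(today), s.patient_id))
    return ordered


def worklist_frame(ordered: Sequence[ReviewSchedule], today: date):
    """Tabulate a worklist (rank, patient, tier, window, overdue, referral)."""
    import pandas as pd

    rows = [{
        "rank": i + 1, "patient_id": s.patient_id, "tier": s.tier.value,
        "due_earliest": s.earliest.isoformat(), "due_latest": s.latest.isoformat(),
        "overdue": s.overdue(today), "referral": s.referral,
    } for i, s in enumerate(ordered)]
    return pd.DataFrame(rows, columns=["rank", "patient_id", "tier",
                                       "due_earliest", "due_latest",
                                       "overdue", "referral"])
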