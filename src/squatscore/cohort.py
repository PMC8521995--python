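"""Respondent grouping, the exercise-habit rule, and descriptive summaries.

Survey respondents report age, gender, how the pandemic changed their
exercise, and their exercise frequency/duration as closed categories.
Respondents split into three age groups (younger ≤ 39 y, middle 40–59 y,
older ≥ 60 y).  Monthly physical activity is estimated as the product of a
sessions-per-month midpoint and a minutes-per-session midpoint for the two
categorical answers, and dichotomised at the recommended 240 min/month into
insufficient vs regular exercise habit (240 exactly counts as regular so
the dichotomy is exhaustive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable

import numpy as np

from .errors import SurveySchemaError

GENDERS = ("men", "women")
EXERCISE_CHANGES = ("increased", "not_changed", "decreased")

#: Sessions-per-month midpoints for the frequency categories.
FREQ_SESSIONS_PER_MONTH: dict[str, float] = {
    "over 5 times/week": 20.0,
    "3-4 times/week": 14.0,
    "1-2 times/week": 6.0,
    "1-2 times/month": 1.5,
}

#: Minutes-per-session midpoints for the duration categories.
DURATION_MINUTES: dict[str, float] = {
    "over 60 min": 60.0,
    "30-50 min": 40.0,
    "10-20 min": 15.0,
    "less than 5 min": 5.0,
}

#: Recommended monthly physical activity (minutes); at/above is "regular".
REGULAR_THRESHOLD_MIN_PER_MONTH = 240.0

AGE_GROUPS = ("younger", "middle", "older")

SURVEY_HEADER = ("age", "gender", "exercise_change", "freq_category", "duration_category")


def _canon(category: str) -> str:
    # accept en-dash variants of the range categories
    return category.strip().replace("–", "-")


@dataclass(frozen=True)
class SurveyRecord:
    age: float
    gender: str
    exercise_change: str
    freq_category: str
    duration_category: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise SurveySchemaError(f"negative age: {self.age}")
        if self.gender not in GENDERS:
            raise SurveySchemaError(f"unknown gender: {self.gender!r}")
        if self.exercise_change not in EXERCISE_CHANGES:
            raise SurveySchemaError(f"unknown exercise_change: {self.exercise_change!r}")
        if _canon(self.freq_category) not in FREQ_SESSIONS_PER_MONTH:
            raise SurveySchemaError(f"unknown freq_category: {self.freq_category!r}")
        if _canon(self.duration_category) not in DURATION_MINUTES:
            raise SurveySchemaError(f"unknown duration_category: {self.duration_category!r}")


def assign_age_group(age: float) -> str:
    """younger (≤ 39 y), middle (40–59 y) or older (≥ 60 y)."""
    if age < 0:
        raise SurveySchemaError(f"negative age: {age}")
    if age <= 39:
        return "younger"
    if age <= 59:
        return "middle"
    return "older"


def monthly_minutes(freq_category: str, duration_category: str) -> float:
    """Estimated physical activity per month, minutes (midpoint × midpoint)."""
    try:
        sessions = FREQ_SESSIONS_PER_MONTH[_canon(freq_category)]
    except KeyError:
        raise SurveySchemaError(f"unknown freq_category: {freq_category!r}") from None
    try:
        minutes = DURATION_MINUTES[_canon(duration_category)]
    except KeyError:
        raise SurveySchemaError(f"unknown duration_category: {duration_category!r}") from None
    return sessions * minutes


def classify_habit(minutes_per_month: float) -> str:
    """'regular' at or above 240 min/month, else 'insufficient'."""
    return "regular" if minutes_per_month >= REGULAR_THRESHOLD_MIN_PER_MONTH else "insufficient"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 67.55 -> 67.6, matching printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_survey_csv(stream: IO[str]) -> list[SurveyRecord]:
    """Read survey records; schema violations name the offending line."""
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        raise SurveySchemaError("empty survey CSV")
    missing = set(SURVEY_HEADER) - set(reader.fieldnames)
    if missing:
        raise SurveySchemaError(f"survey CSV missing column(s): {sorted(missing)}")
    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            records.append(
                SurveyRecord(
                    age=float(row["age"]),
                    gender=row["gender"].strip(),
                    exercise_change=row["exercise_change"].strip(),
                    freq_category=row["freq_category"],
                    duration_category=row["duration_category"],
                )
            )
        except (SurveySchemaError, ValueError) as exc:
            raise SurveySchemaError(f"line {lineno}: {exc}") from None
    if not records:
        raise SurveySchemaError("survey CSV has no data rows")
    return records


@dataclass
class CohortSummary:
    """Counts and percentages per age group plus the pooled column."""

    groups: dict[str, dict]

    def to_dict(self) -> dict:
        return self.groups

    def to_rows(self) -> list[dict]:
        """Long-format rows (group, section, category, n, pct) for CSV export."""
        rows = []
        for group, summary in self.groups.items():
            for section in ("gender", "exercise_change", "habit"):
                for category, stats in summary[section].items():
                    rows.append(
                        {
                            "group": group,
                            "section": section,
                            "category": category,
                            "n": stats["n"],
                            "pct": stats["pct"],
                        }
                    )
        return rows


def _category_block(values: Iterable[str], categories: tuple[str, ...]) -> dict:
    values = list(values)
    n = len(values)
    block = {}
    for cat in categories:
        k = sum(1 for v in values if v == cat)
        block[cat] = {"n": k, "pct": round_half_up(100.0 * k / n) if n else 0.0}
    return block


def summarize(records: list[SurveyRecord]) -> CohortSummary:
    """Descriptive summary by age group: n, gender, exercise change, habit, age stats."""
    if not records:
        raise SurveySchemaError("no records to summarize")
    groups: dict[str, dict] = {}
    membership = {g: [r for r in records if assign_age_group(r.age) == g] for g in AGE_GROUPS}
    membership["all"] = list(records)
    for name, recs in membership.items():
        if not recs:
            groups[name] = {"n": 0}
            continue
        ages = np.array([r.age for r in recs], dtype=float)
        habits = [classify_habit(monthly_minutes(r.freq_category, r.duration_category)) for r in recs]
        groups[name] = {
            "n": len(recs),
            "age": {
                "mean": round_half_up(float(ages.mean())),
                "sd": round_half_up(float(ages.std(ddof=1))) if len(recs) > 1 else 0.0,
                "min": float(ages.min()),
                "max": float(ages.max()),
            },
            "gender": _category_block((r.gender for r in recs), GENDERS),
            "exercise_change": _category_block((r.exercise_change for r in recs), EXERCISE_CHANGES),
            "habit": _category_block(habits, ("insufficient", "regular")),
        }
    return CohortSummary(groups)
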