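"""Screening-history classification.

Each woman's cytology history is reduced to a *maximum screening interval*:
the longest stretch of the screening window containing no adequate smear
(gaps to the window boundaries count).  The interval, together with age at
the reference (diagnosis) date, assigns one of four regularity categories:

===============  ==========================================================
Age at reference  Rule
===============  ==========================================================
35-64            window = 15 years before diagnosis; regular if the maximum
                 interval is <= 3.5 y (ages 35-49) or <= 5.5 y (50-64);
                 irregular if <= 7.5 y; very irregular if <= 13 y; else not
                 screened.
>= 65            window = ages 50-64, with the 5.5 / 7.5 / 13 y cut-offs.
25.5-35          attendance per 3-year age slice: regular iff every
                 required slice (22.5-25.5, 25.5-28.5, 28.5-31.5, depending
                 on current age) contains an adequate smear; irregular iff
                 at least one adequate smear in the window but not regular;
                 otherwise not screened.  There is no very-irregular level.
===============  ==========================================================

Ties at a cut-off resolve toward the more regular category (the published
rules use "<=").  Inadequate smears never count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .tables import (
    IRREGULAR,
    NOT_SCREENED,
    REGULAR,
    VERY_IRREGULAR,
    YEAR_DAYS,
)

MIN_AGE = 25.5

# Maximum-interval cut-offs (years): regular / irregular / very irregular.
CUTOFFS_35_49 = (3.5, 7.5, 13.0)
CUTOFFS_50_PLUS = (5.5, 7.5, 13.0)

# 3-year age slices for the under-35 attendance rule.
YOUNG_SLICES = ((22.5, 25.5), (25.5, 28.5), (28.5, 31.5))


@dataclass(frozen=True)
class SmearRecord:
    """One dated cytology test; ``adequate`` is False for inadequate tests."""

    woman_id: str
    date: dt.date
    adequate: bool


@dataclass(frozen=True)
class ScreeningWindow:
    """Half-open date window [start, end] over which smears are considered."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("screening window must have start < end")

    @property
    def length_years(self) -> float:
        return (self.end - self.start).days / YEAR_DAYS


def years_between(a: dt.date, b: dt.date) -> float:
    return (b - a).days / YEAR_DAYS


def age_at(birth_date: dt.date, on: dt.date) -> float:
    return years_between(birth_date, on)


def date_at_age(birth_date: dt.date, age_years: float) -> dt.date:
    return birth_date + dt.timedelta(days=round(age_years * YEAR_DAYS))


def screening_window(
    birth_date: dt.date, reference_date: dt.date, window_years: float = 15.0,
    min_age: float = MIN_AGE,
) -> ScreeningWindow:
    """The screening window for a woman given her age at the reference date.

    Ages below 65 use a lookback of ``window_years`` before the reference
    date (sensitivity analyses shorten it); from 65 the window is ages
    50-64 regardless of the reference date.  Under-35 windows start at age
    22.5 and end at the slice boundary relevant to the woman's current age.
    ``min_age`` may be lowered to 24.5 for the widened-inclusion
    sensitivity analysis; such women's windows are truncated at the
    reference date.
    """
    age = age_at(birth_date, reference_date)
    if age < min_age:
        raise ValueError(f"age {age:.2f} below the study minimum of {min_age}")
    if age < 35.0:
        if age < 28.5:
            end_age = 25.5
        elif age < 31.5:
            end_age = 28.5
        else:
            end_age = 31.5
        end = min(date_at_age(birth_date, end_age), reference_date)
        return ScreeningWindow(date_at_age(birth_date, 22.5), end)
    if age < 65.0:
        return ScreeningWindow(
            reference_date - dt.timedelta(days=round(window_years * YEAR_DAYS)),
            reference_date,
        )
    return ScreeningWindow(date_at_age(birth_date, 50.0), date_at_age(birth_date, 65.0))


def max_adequate_interval(smears, window: ScreeningWindow) -> float:
    """Longest smear-free period (years) within the window.

    Considers adequate smears falling inside the window; the gaps from the
    window start to the first such smear and from the last to the window
    end both count, so a woman with no adequate smear scores the full
    window length.
    """
    dates = sorted(
        s.date for s in smears if s.adequate and window.start <= s.date <= window.end
    )
    if not dates:
        return window.length_years
    anchors = [window.start, *dates, window.end]
    return max(
        years_between(a, b) for a, b in zip(anchors[:-1], anchors[1:])
    )


def _classify_interval(max_interval: float, cutoffs) -> str:
    reg, irr, virr = cutoffs
    if max_interval <= reg:
        return REGULAR
    if max_interval <= irr:
        return IRREGULAR
    if max_interval <= virr:
        return VERY_IRREGULAR
    return NOT_SCREENED


def _required_slices(age: float):
    if age < 28.5:
        return YOUNG_SLICES[:1]
    if age < 31.5:
        return YOUNG_SLICES[:2]
    return YOUNG_SLICES


def _classify_young(birth_date: dt.date, smears, window: ScreeningWindow, age: float) -> str:
    adequate_ages = [
        age_at(birth_date, s.date)
        for s in smears
        if s.adequate and window.start <= s.date <= window.end
    ]
    if not adequate_ages:
        return NOT_SCREENED
    slices = _required_slices(age)
    covered = all(any(lo <= a < hi for a in adequate_ages) for lo, hi in slices)
    return REGULAR if covered else IRREGULAR


def classify(
    birth_date: dt.date,
    reference_date: dt.date,
    smears,
    window_years: float = 15.0,
    min_age: float = MIN_AGE,
) -> tuple[str, float]:
    """Assign the screening-regularity category for one woman.

    Returns ``(category, max_interval_years)``.  For under-35 women the
    interval is still reported but the category comes from the per-slice
    attendance rule.
    """
    age = age_at(birth_date, reference_date)
    window = screening_window(birth_date, reference_date, window_years, min_age)
    interval = max_adequate_interval(smears, window)
    if age < 35.0:
        return _classify_young(birth_date, smears, window, age), interval
    any_adequate = any(
        s.adequate and window.start <= s.date <= window.end for s in smears
    )
    if not any_adequate:
        # "no screen in window" is not-screened even when a shortened
        # sensitivity window is itself below the 13-year cut-off
        return NOT_SCREENED, interval
    cutoffs = CUTOFFS_35_49 if age < 50.0 else CUTOFFS_50_PLUS
    return _classify_interval(interval, cutoffs), interval


def classify_cohort(women, smears_by_woman, window_years: float = 15.0, min_age: float = MIN_AGE):
    """Classify every woman in a cohort.

    ``women`` is an iterable of objects with ``woman_id``, ``birth_date``
    and ``reference_date``; returns ``{woman_id: (category, interval)}``.
    """
    return {
        w.woman_id: classify(
            w.birth_date,
            w.reference_date,
            smears_by_woman.get(w.woman_id, ()),
            window_years,
            min_age,
        )
        for w in women
    }
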