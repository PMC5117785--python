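"""Synthetic matched case-control cohorts with known ground truth.

The confidential audit data cannot be shipped, so this module generates
age-matched sets (one case, one or two cancer-free controls) whose smear
histories *realize* a known screening-regularity category, and whose case
stages and categories are drawn so that, within each age band, the induced
category-given-stage odds versus the never-screened category equal a
configured true odds ratio.  Every downstream stage of the pipeline --
classification, conditional logistic regression, reallocation, projection
-- can therefore be checked against the generating parameters.

Generative model per matched set:

1. draw an age band, then the case's age uniformly within it; controls
   share the birth date (age matching is exact to the day, a harmless
   idealization of the real +/- tolerance);
2. draw the case's (stage, category) with probability proportional to
   ``stage_dist[s] * prevalence[j] * true_or[s, j]`` (the exponential-tilt
   construction that makes the conditional OR of category j vs 0 equal
   ``true_or`` exactly);
3. draw each control's category from ``prevalence``;
4. blank the case's stage with probability ``missing_stage_fraction``;
5. construct adequate smear dates that the interval classifier maps back
   to exactly the drawn category, plus a few inadequate smears that must
   be ignored.

Category prevalences default to the control distribution implied by the
packaged England-audit tables, so the generator's default conditions match
the study the pipeline targets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tables as T
from .classifier import (
    MIN_AGE,
    YOUNG_SLICES,
    SmearRecord,
    date_at_age,
    screening_window,
)

REFERENCE_EPOCH = dt.date(2010, 1, 1)  # middle of the 2007-2013 accrual window


@dataclass(frozen=True)
class Woman:
    woman_id: str
    set_id: int
    is_case: bool
    birth_date: dt.date
    reference_date: dt.date
    stage: str | None  # cases only; STAGE_UNKNOWN when blanked
    smears: tuple[SmearRecord, ...] = ()
    # ground truth, carried for closed-loop testing only
    true_category: str | None = None


@dataclass(frozen=True)
class MatchedSet:
    set_id: int
    women: tuple[Woman, ...]  # case first

    @property
    def case(self) -> Woman:
        return self.women[0]

    @property
    def controls(self) -> tuple[Woman, ...]:
        return self.women[1:]


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``true_or`` maps ``(age_band, stage, category)`` to the odds ratio of a
    stage-specific diagnosis for category j versus never-screened; the
    never-screened entries must be 1.
    """

    n_sets: int = 1000
    seed: int = 0
    age_distribution: dict[str, float] = field(default_factory=dict)
    control_category_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    true_or: dict[tuple[str, str, str], float] = field(default_factory=dict)
    stage_distribution: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_stage_fraction: float = 0.136
    single_control_fraction: float = 0.01
    window_years: float = 15.0

    def __post_init__(self) -> None:
        for band, prev in self.control_category_prevalence.items():
            if abs(sum(prev.values()) - 1.0) > 1e-9:
                raise ValueError(f"category prevalence in band {band} must sum to 1")
            if band == "25.5-34" and prev.get(T.VERY_IRREGULAR, 0.0) > 0:
                raise ValueError("ages 25.5-34 have no very_irregular level")
        for band, dist in self.stage_distribution.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"stage distribution in band {band} must sum to 1")
        for (band, stage, cat), or_ in self.true_or.items():
            if cat == T.NOT_SCREENED and or_ != 1.0:
                raise ValueError("true OR for the never-screened category must be 1")
            if or_ <= 0:
                raise ValueError(f"true OR must be positive in {(band, stage, cat)}")

    @classmethod
    def from_fixture(cls, name: str = "england_audit", **overrides) -> "SimConfig":
        """Default conditions implied by the packaged audit aggregates.

        The true ORs are the published stage-specific ORs; the control
        category prevalence in each band is the one implied by the case
        distribution under the tilting model (prevalence proportional to
        cases divided by OR, summed over stages); the baseline stage
        distribution is proportional to never-screened case counts.
        """
        counts, ors, _, _ = T.load_fixture_tables(name)
        totals = T.fixture_totals(name)
        age_w, prev, true_or, stage_dist = {}, {}, {}, {}
        for band in counts.bands():
            stages = counts.stages(band)
            age_w[band] = counts.band_total(band, include_unknown=False)
            implied = {}
            for cat in T.CATEGORIES:
                mass = sum(
                    counts.get(band, s, cat) / ors.get(band, s, cat).odds_ratio
                    for s in stages
                    if counts.get(band, s, cat) > 0
                )
                if mass > 0:
                    implied[cat] = mass
            z = sum(implied.values())
            prev[band] = {c: m / z for c, m in implied.items()}
            base = {s: counts.get(band, s, T.NOT_SCREENED) for s in stages}
            zb = sum(base.values())
            stage_dist[band] = {s: v / zb for s, v in base.items()}
            for s in stages:
                for cat in prev[band]:
                    true_or[(band, s, cat)] = ors.get(band, s, cat).odds_ratio
        za = sum(age_w.values())
        cfg = cls(
            age_distribution={b: w / za for b, w in age_w.items()},
            control_category_prevalence=prev,
            true_or=true_or,
            stage_distribution=stage_dist,
            missing_stage_fraction=totals["unknown_stage_cases"] / totals["total_cases"],
        )
        return replace(cfg, **overrides) if overrides else cfg


class GenerationError(ValueError):
    """A requested category cannot be realized under the window geometry."""


# ---------------------------------------------------------------------------
# smear-history realization
# ---------------------------------------------------------------------------

_GAP_RANGE = {  # target max-gap range (years) per category, 35+ rules
    T.IRREGULAR: (None, 7.5),  # lower bound is the age-dependent regular cut-off
    T.VERY_IRREGULAR: (7.5, 13.0),
}
_MARGIN = 0.1  # keeps day-rounded dates clear of category boundaries


def _gap_positions(rng: np.random.Generator, g: float, length: float) -> list[float]:
    """Offsets in [0, length] whose max gap (boundaries included) is g."""
    pos = [g]
    while length - pos[-1] > 0.92 * g:
        pos.append(pos[-1] + rng.uniform(0.4 * g, 0.9 * g))
    return pos


def _realize_interval_history(
    rng: np.random.Generator,
    window,
    category: str,
    regular_cutoff: float,
    band: str,
) -> list[dt.date]:
    W = window.length_years
    if category == T.NOT_SCREENED:
        return []
    if category == T.REGULAR:
        lo, hi = 0.0, regular_cutoff
    else:
        lo, hi = _GAP_RANGE[category]
        if lo is None:
            lo = regular_cutoff
    hi = min(hi, W)
    if lo + 2 * _MARGIN >= hi:
        raise GenerationError(
            f"cannot realize category {category!r} in band {band}: "
            f"window of {W:.1f}y leaves no room for a gap in ({lo}, {hi}]"
        )
    g = rng.uniform(lo + _MARGIN, hi - _MARGIN) if lo > 0 else rng.uniform(0.45 * hi, hi - _MARGIN)
    offsets = _gap_positions(rng, g, W)
    return [window.start + dt.timedelta(days=round(o * T.YEAR_DAYS)) for o in offsets]


def _realize_young_history(
    rng: np.random.Generator,
    birth_date: dt.date,
    age: float,
    category: str,
    band: str,
) -> list[dt.date]:
    if age < 28.5:
        n_slices = 1
    elif age < 31.5:
        n_slices = 2
    else:
        n_slices = 3
    slices = YOUNG_SLICES[:n_slices]
    if category == T.NOT_SCREENED:
        return []
    if category == T.REGULAR:
        chosen = list(range(n_slices))
    elif category == T.IRREGULAR:
        if n_slices == 1:
            raise GenerationError(
                f"cannot realize 'irregular' in band {band} under age 28.5: "
                "a single required slice leaves no intermediate category"
            )
        # at least one smear, but at least one required slice left uncovered
        k = int(rng.integers(1, n_slices))
        chosen = sorted(rng.choice(n_slices, size=k, replace=False).tolist())
    else:
        raise GenerationError(f"category {category!r} undefined in band {band}")
    dates = []
    for i in chosen:
        lo, hi = slices[i]
        a = rng.uniform(lo + _MARGIN, hi - _MARGIN)
        dates.append(date_at_age(birth_date, a))
    return dates


def realize_smears(
    rng: np.random.Generator,
    woman_id: str,
    birth_date: dt.date,
    reference_date: dt.date,
    category: str,
    band: str,
    window_years: float = 15.0,
) -> tuple[SmearRecord, ...]:
    """Construct a smear history that classifies as exactly ``category``."""
    age = (reference_date - birth_date).days / T.YEAR_DAYS
    window = screening_window(birth_date, reference_date, window_years)
    if age < 35.0:
        dates = _realize_young_history(rng, birth_date, age, category, band)
    else:
        cutoff = 3.5 if age < 50.0 else 5.5
        dates = _realize_interval_history(rng, window, category, cutoff, band)
    records = [SmearRecord(woman_id, d, True) for d in dates]
    # a sprinkling of inadequate tests the classifier must ignore
    for _ in range(int(rng.integers(0, 3))):
        offset = rng.uniform(0.0, window.length_years)
        d = window.start + dt.timedelta(days=round(offset * T.YEAR_DAYS))
        records.append(SmearRecord(woman_id, d, False))
    return tuple(sorted(records, key=lambda r: r.date))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _feasible(prev: dict[str, float], band: str, age: float) -> dict[str, float]:
    """Prevalence restricted to categories realizable at this exact age."""
    if band == "25.5-34" and age < 28.5 and T.IRREGULAR in prev:
        out = {c: p for c, p in prev.items() if c != T.IRREGULAR}
        z = sum(out.values())
        return {c: p / z for c, p in out.items()}
    return prev


def _draw(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def simulate_cohort(config: SimConfig) -> list[MatchedSet]:
    """Generate ``config.n_sets`` matched sets under the configured truth."""
    rng = np.random.default_rng(config.seed)
    sets = []
    for set_id in range(config.n_sets):
        band = _draw(rng, config.age_distribution)
        b = T.AgeBand.from_label(band)
        age = rng.uniform(max(b.lower, MIN_AGE), b.upper)
        reference_date = REFERENCE_EPOCH + dt.timedelta(days=int(rng.integers(-900, 900)))
        birth_date = reference_date - dt.timedelta(days=round(age * T.YEAR_DAYS))
        age = (reference_date - birth_date).days / T.YEAR_DAYS  # after day rounding

        prev = _feasible(config.control_category_prevalence[band], band, age)
        # joint case draw: P(s, j) oc stage_dist[s] * prev[j] * true_or[s, j]
        stage_keys, cat_keys = list(config.stage_distribution[band]), list(prev)
        weights = {
            (s, j): config.stage_distribution[band][s]
            * prev[j]
            * config.true_or[(band, s, j)]
            for s in stage_keys
            for j in cat_keys
        }
        stage, case_cat = _draw(rng, weights)  # type: ignore[misc]

        recorded_stage = stage
        if rng.uniform() < config.missing_stage_fraction:
            recorded_stage = T.STAGE_UNKNOWN

        n_controls = 1 if rng.uniform() < config.single_control_fraction else 2
        women = []
        for k in range(1 + n_controls):
            is_case = k == 0
            wid = f"w{set_id:06d}-{k}"
            cat = case_cat if is_case else _draw(rng, prev)
            smears = realize_smears(
                rng, wid, birth_date, reference_date, cat, band, config.window_years
            )
            women.append(
                Woman(
                    woman_id=wid,
                    set_id=set_id,
                    is_case=is_case,
                    birth_date=birth_date,
                    reference_date=reference_date,
                    stage=recorded_stage if is_case else None,
                    smears=smears,
                    true_category=cat,
                )
            )
        sets.append(MatchedSet(set_id, tuple(women)))
    return sets


# ---------------------------------------------------------------------------
# cohort IO
# ---------------------------------------------------------------------------


def cohort_frames(sets) -> tuple[pd.DataFrame, pd.DataFrame]:
    wrows, srows, seen = [], [], set()
    for mset in sets:
        for w in mset.women:
            if w.woman_id in seen:
                raise ValueError(f"duplicate woman_id {w.woman_id!r}")
            seen.add(w.woman_id)
            wrows.append(
                {
                    "woman_id": w.woman_id,
                    "set_id": w.set_id,
                    "is_case": int(w.is_case),
                    "birth_date": w.birth_date.isoformat(),
                    "reference_date": w.reference_date.isoformat(),
                    "stage": w.stage or "",
                }
            )
            for s in w.smears:
                srows.append(
                    {
                        "woman_id": w.woman_id,
                        "date": s.date.isoformat(),
                        "adequate": int(s.adequate),
                    }
                )
    women = pd.DataFrame(
        wrows,
        columns=["woman_id", "set_id", "is_case", "birth_date", "reference_date", "stage"],
    )
    smears = pd.DataFrame(srows, columns=["woman_id", "date", "adequate"])
    return women, smears


def write_cohort(sets, directory) -> None:
    """Write women.csv and smears.csv (ISO-8601 dates; lossless round-trip)."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    women, smears = cohort_frames(sets)
    women.to_csv(d / "women.csv", index=False)
    smears.to_csv(d / "smears.csv", index=False)


def read_cohort(directory) -> list[MatchedSet]:
    from pathlib import Path

    d = Path(directory)
    women = pd.read_csv(d / "women.csv", keep_default_na=False)
    smears = pd.read_csv(d / "smears.csv", keep_default_na=False)
    by_woman: dict[str, list[SmearRecord]] = {}
    for r in smears.itertuples():
        by_woman.setdefault(str(r.woman_id), []).append(
            SmearRecord(str(r.woman_id), dt.date.fromisoformat(str(r.date)), bool(int(r.adequate)))
        )
    by_set: dict[int, list[Woman]] = {}
    for r in women.itertuples():
        w = Woman(
            woman_id=str(r.woman_id),
            set_id=int(r.set_id),
            is_case=bool(int(r.is_case)),
            birth_date=dt.date.fromisoformat(str(r.birth_date)),
            reference_date=dt.date.fromisoformat(str(r.reference_date)),
            stage=str(r.stage) or None,
            smears=tuple(sorted(by_woman.get(str(r.woman_id), ()), key=lambda s: s.date)),
        )
        by_set.setdefault(w.set_id, []).append(w)
    sets = []
    for set_id in sorted(by_set):
        members = by_set[set_id]
        members.sort(key=lambda w: (not w.is_case, w.woman_id))
        sets.append(MatchedSet(set_id, tuple(members)))
    return sets
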