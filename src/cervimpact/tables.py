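"""Domain vocabulary and table containers for screening-impact estimation.

The analysis is driven by three aggregate tables indexed by age band at
diagnosis, FIGO stage, and screening-regularity category:

* :class:`CaseCountTable` -- numbers of audit cases per cell (fractional
  counts are allowed once percentages are converted or unknown-stage cases
  are reallocated);
* :class:`ORTable` -- odds ratios of a stage-specific cancer diagnosis for
  each screening category versus never-screened, with Wald CIs;
* :class:`FatalityTable` -- 5-year case fatality, i.e. one minus 5-year
  relative survival, per age band and stage;
* :class:`ObservedDeaths` -- annual cervical cancer deaths by age band at
  death, used to convert relative risks into absolute deaths.

A packaged fixture (``england_audit``) carries the published England audit
aggregates so that the projection pipeline can be run without access to the
confidential individual-level records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

# FIGO stages, ordered by severity.  "unknown" never participates in the
# ordering; it exists only until reallocation.
STAGE_1A = "1A"
STAGE_1B = "1B"
STAGE_2 = "2"
STAGE_3PLUS = "3plus"
STAGE_UNKNOWN = "unknown"
STAGES = (STAGE_1A, STAGE_1B, STAGE_2, STAGE_3PLUS)
STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}

# Screening-regularity categories with their ordinal trend score
# (0 = not screened, ascending regularity).
NOT_SCREENED = "not_screened"
VERY_IRREGULAR = "very_irregular"
IRREGULAR = "irregular"
REGULAR = "regular"
CATEGORIES = (NOT_SCREENED, VERY_IRREGULAR, IRREGULAR, REGULAR)
CATEGORY_SCORE = {c: i for i, c in enumerate(CATEGORIES)}

# Sentinel category for unknown-stage rows whose screening history split is
# not available (aggregate fixtures only carry a per-band unknown total).
ALL_CATEGORIES = "all"

# Age bands at diagnosis used by the odds-ratio tables.
OR_BANDS = ("25.5-34", "35-64", "65-79")
# Finer bands on which case fatality is tabulated.
SURVIVAL_BANDS = ("25.5-34", "35-49", "50-64", "65-69", "70-79")
# Mapping used to collapse survival bands onto OR bands (unweighted mean by
# default; see FatalityTable.collapse).
SURVIVAL_TO_OR_BANDS = {
    "25.5-34": ("25.5-34",),
    "35-64": ("35-49", "50-64"),
    "65-79": ("65-69", "70-79"),
}

YEAR_DAYS = 365.25


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lower, upper) in decimal years."""

    lower: float
    upper: float
    role: str = "diagnosis"  # diagnosis | death | survival

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate age band [{self.lower}, {self.upper})")

    def __contains__(self, age: float) -> bool:
        return self.lower <= age < self.upper

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"

        # Conventional labels print the upper bound inclusively ("35-64"
        # for [35, 65)) when the bound is an integer.
        hi = self.upper - 1 if float(self.upper).is_integer() else self.upper
        return f"{fmt(self.lower)}-{fmt(hi)}"

    @classmethod
    def from_label(cls, label: str, role: str = "diagnosis") -> "AgeBand":
        lo_s, hi_s = label.split("-")
        lo, hi = float(lo_s), float(hi_s)
        upper = hi + 1 if hi.is_integer() else hi
        return cls(lo, upper, role)

    def shifted(self, years: float = 5.0) -> "AgeBand":
        """The age-at-death band for this age-at-diagnosis band.

        Deaths within five years of diagnosis occur up to five years after
        the diagnosis ages, so the upper bound shifts while the lower bound
        stays: diagnosis at [25, 35) maps to death at [25, 40).
        """
        return AgeBand(self.lower, self.upper + years, role="death")


def band_for_age(age: float, labels: tuple[str, ...] = OR_BANDS) -> str:
    for label in labels:
        if age in AgeBand.from_label(label):
            return label
    raise ValueError(f"age {age} outside the tabulated bands {labels}")


def _check_cell(band: str, stage: str, category: str) -> None:
    if stage == STAGE_UNKNOWN:
        if category != ALL_CATEGORIES:
            raise ValueError("unknown-stage rows carry the 'all' category sentinel")
    elif stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    elif category not in CATEGORIES:
        raise ValueError(f"unknown screening category {category!r}")


@dataclass
class CaseCountTable:
    """Case counts by (age band, stage, screening category).

    Counts are stored as floats: converting the published per-stage
    percentages to counts, and reallocating unknown-stage cases, both yield
    fractional cells, and the downstream projections are linear in the
    counts so no rounding is ever applied.
    """

    entries: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (band, stage, cat), n in self.entries.items():
            _check_cell(band, stage, cat)
            if n < 0:
                raise ValueError(f"negative count in cell {(band, stage, cat)}")

    # -- accessors -------------------------------------------------------
    def get(self, band: str, stage: str, category: str, default: float = 0.0) -> float:
        return self.entries.get((band, stage, category), default)

    def bands(self) -> list[str]:
        return sorted({b for b, _, _ in self.entries})

    def stages(self, band: str) -> list[str]:
        found = {s for b, s, _ in self.entries if b == band and s != STAGE_UNKNOWN}
        return sorted(found, key=STAGE_ORDER.get)

    def categories(self, band: str, stage: str) -> list[str]:
        found = {c for b, s, c in self.entries if b == band and s == stage}
        return sorted(found, key=lambda c: CATEGORY_SCORE.get(c, -1))

    def stage_total(self, band: str, stage: str) -> float:
        return sum(n for (b, s, _), n in self.entries.items() if b == band and s == stage)

    def band_total(self, band: str, include_unknown: bool = True) -> float:
        return sum(
            n
            for (b, s, _), n in self.entries.items()
            if b == band and (include_unknown or s != STAGE_UNKNOWN)
        )

    def total(self, include_unknown: bool = True) -> float:
        return sum(self.band_total(b, include_unknown) for b in self.bands())

    def unknown(self, band: str) -> float:
        return self.entries.get((band, STAGE_UNKNOWN, ALL_CATEGORIES), 0.0)

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_band": b, "stage": s, "category": c, "count": n}
            for (b, s, c), n in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["age_band", "stage", "category", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CaseCountTable":
        entries = {
            (str(r.age_band), str(r.stage), str(r.category)): float(r.count)
            for r in df.itertuples()
        }
        return cls(entries)


@dataclass(frozen=True)
class ORCell:
    """One odds ratio with its Wald 95% CI and log-scale standard error."""

    odds_ratio: float
    lo: float
    hi: float
    se_log: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.lo <= self.odds_ratio <= self.hi):
            raise ValueError("CI must bracket the point estimate")
        if self.se_log < 0:
            raise ValueError("se_log must be non-negative")


REFERENT_CELL = ORCell(1.0, 1.0, 1.0, 0.0)


def se_log_from_ci(lo: float, hi: float) -> float:
    """Log-scale SE implied by a Wald 95% CI: (ln hi - ln lo) / (2 * 1.96)."""
    return (math.log(hi) - math.log(lo)) / (2 * 1.96)


@dataclass
class ORTable:
    """Odds ratios by (age band, stage, screening category).

    The never-screened category is the referent in every stratum and its
    cell is exactly 1 with zero log-scale variance.
    """

    entries: dict[tuple[str, str, str], ORCell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (band, stage, cat), cell in self.entries.items():
            _check_cell(band, stage, cat)
            if cat == NOT_SCREENED and cell != REFERENT_CELL:
                raise ValueError(f"referent cell {(band, stage)} must be exactly 1")

    def get(self, band: str, stage: str, category: str) -> ORCell:
        if category == NOT_SCREENED:
            return REFERENT_CELL
        return self.entries[(band, stage, category)]

    def has(self, band: str, stage: str, category: str) -> bool:
        return category == NOT_SCREENED or (band, stage, category) in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "age_band": b,
                "stage": s,
                "category": c,
                "or": cell.odds_ratio,
                "lo": cell.lo,
                "hi": cell.hi,
                "se_log": cell.se_log,
            }
            for (b, s, c), cell in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["age_band", "stage", "category", "or", "lo", "hi", "se_log"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ORTable":
        df = df.rename(columns={"or": "odds_ratio"})  # "or" is a keyword
        entries = {}
        for r in df.itertuples():
            entries[(str(r.age_band), str(r.stage), str(r.category))] = ORCell(
                float(r.odds_ratio), float(r.lo), float(r.hi), float(r.se_log)
            )
        return cls(entries)


@dataclass
class FatalityTable:
    """5-year case fatality rho = 1 - relative survival by (age band, stage)."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    # stage labels are not restricted to the FIGO set: raked grids may use
    # arbitrary stage groupings
    def __post_init__(self) -> None:
        for (band, stage), rho in self.entries.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"fatality outside [0, 1] in {(band, stage)}")

    def get(self, band: str, stage: str) -> float:
        return self.entries[(band, stage)]

    def bands(self) -> list[str]:
        return sorted({b for b, _ in self.entries})

    def collapse(
        self,
        mapping: dict[str, tuple[str, ...]] = SURVIVAL_TO_OR_BANDS,
        weights: dict[str, float] | None = None,
    ) -> "FatalityTable":
        """Collapse fine survival bands onto coarser bands.

        Each target band's fatality is the mean of its source bands'
        fatalities per stage -- unweighted unless per-source-band case
        ``weights`` are supplied.
        """
        out: dict[tuple[str, str], float] = {}
        stages = {s for _, s in self.entries}
        for target, sources in mapping.items():
            for stage in stages:
                if weights is None:
                    w = {b: 1.0 for b in sources}
                else:
                    w = {b: weights[b] for b in sources}
                wsum = sum(w.values())
                out[(target, stage)] = (
                    sum(self.entries[(b, stage)] * w[b] for b in sources) / wsum
                )
        return FatalityTable(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_band": b, "stage": s, "rho": rho}
            for (b, s), rho in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["age_band", "stage", "rho"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FatalityTable":
        return cls(
            {(str(r.age_band), str(r.stage)): float(r.rho) for r in df.itertuples()}
        )


@dataclass
class ObservedDeaths:
    """Annual observed deaths by age band at death, plus the all-ages total.

    The all-ages total may exceed the sum over listed bands: deaths from
    cancers diagnosed outside the band range (under 25 or over 79) are
    unaffected by screening and are carried through projections unchanged.
    """

    entries: dict[str, float] = field(default_factory=dict)
    all_ages: float = 0.0
    # published in-band total, when it differs from the band sum by rounding
    # (annual averages are rounded per band before printing)
    in_band_total: float | None = None

    def __post_init__(self) -> None:
        if self.all_ages < sum(self.entries.values()) - 1.5:
            raise ValueError("all-ages deaths below the sum of listed bands")

    def in_bands(self) -> float:
        if self.in_band_total is not None:
            return self.in_band_total
        return sum(self.entries.values())

    def out_of_bands(self) -> float:
        return self.all_ages - self.in_bands()

    def to_frame(self) -> pd.DataFrame:
        rows = [{"death_band": b, "deaths": d} for b, d in sorted(self.entries.items())]
        if self.in_band_total is not None:
            rows.append({"death_band": "in_band_total", "deaths": self.in_band_total})
        rows.append({"death_band": "all_ages", "deaths": self.all_ages})
        return pd.DataFrame(rows, columns=["death_band", "deaths"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedDeaths":
        entries, all_ages, in_band = {}, 0.0, None
        for r in df.itertuples():
            if str(r.death_band) == "all_ages":
                all_ages = float(r.deaths)
            elif str(r.death_band) == "in_band_total":
                in_band = float(r.deaths)
            else:
                entries[str(r.death_band)] = float(r.deaths)
        return cls(entries, all_ages, in_band)


_TABLE_TYPES = {
    "counts": CaseCountTable,
    "ors": ORTable,
    "fatality": FatalityTable,
    "deaths": ObservedDeaths,
}


def write_table(table, path) -> None:
    """Write any table container to CSV (full float precision)."""
    table.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_table(kind: str, path) -> object:
    """Read a table container written by :func:`write_table`.

    ``kind`` is one of ``counts``, ``ors``, ``fatality``, ``deaths``.
    """
    try:
        cls = _TABLE_TYPES[kind]
    except KeyError:
        raise ValueError(f"unknown table kind {kind!r}") from None
    df = pd.read_csv(path)
    return cls.from_frame(df)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("england_audit",)


def _fixture_dir(name: str):
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return resources.files("cervimpact") / "fixtures" / name


def fixture_totals(name: str = "england_audit") -> dict[str, float]:
    df = pd.read_csv(_fixture_dir(name) / "totals.csv")
    return dict(zip(df["quantity"], df["value"].astype(float)))


def load_fixture_tables(
    name: str = "england_audit",
) -> tuple[CaseCountTable, ORTable, FatalityTable, ObservedDeaths]:
    """Load the packaged aggregate tables for a named study fixture.

    Case counts are reconstructed as ``n_stage * pct / 100`` and kept
    fractional.  Unknown-stage cases (whose per-band breakdown was not
    published) are split across age bands proportionally to each band's
    staged total and stored under the ``unknown`` stage with the ``all``
    category sentinel, awaiting reallocation.
    """
    fdir = _fixture_dir(name)
    ors_df = pd.read_csv(fdir / "stage_ors.csv")
    totals = fixture_totals(name)

    # printed per-stage category percentages carry rounding (their sums are
    # 99.9-100.1); normalizing by the printed sum makes each stage's counts
    # add up to its printed n exactly
    pct_sums = ors_df.groupby(["age_band", "stage"])["pct_cases"].transform("sum")
    counts: dict[tuple[str, str, str], float] = {}
    ors: dict[tuple[str, str, str], ORCell] = {}
    for r, pct_sum in zip(ors_df.itertuples(), pct_sums):
        band, stage, cat = str(r.age_band), str(r.stage), str(r.category)
        counts[(band, stage, cat)] = float(r.n_stage) * float(r.pct_cases) / float(pct_sum)
        if cat == NOT_SCREENED:
            ors[(band, stage, cat)] = REFERENT_CELL
        else:
            lo, hi = float(r.lo), float(r.hi)
            ors[(band, stage, cat)] = ORCell(
                float(r.odds_ratio), lo, hi, se_log_from_ci(lo, hi)
            )

    count_table = CaseCountTable(counts)
    staged_total = totals["staged_cases"]
    for band in count_table.bands():
        band_staged = sum(
            float(r.n_stage)
            for r in ors_df.itertuples()
            if str(r.age_band) == band and str(r.category) == NOT_SCREENED
        )
        counts[(band, STAGE_UNKNOWN, ALL_CATEGORIES)] = (
            totals["unknown_stage_cases"] * band_staged / staged_total
        )
    count_table = CaseCountTable(counts)

    fat_df = pd.read_csv(fdir / "case_fatality.csv")
    fatality = FatalityTable(
        {
            (str(r.age_band), str(r.stage)): float(r.fatality_pct) / 100.0
            for r in fat_df.itertuples()
        }
    )

    proj = pd.read_csv(fdir / "mortality_projection.csv")
    deaths = ObservedDeaths(
        {str(r.death_band): float(r.observed_deaths) for r in proj.itertuples()},
        all_ages=totals["observed_deaths_all_ages"],
        in_band_total=totals.get("observed_deaths_in_bands"),
    )
    return count_table, ORTable(ors), fatality, deaths


def load_mortality_projection(name: str = "england_audit") -> pd.DataFrame:
    """The published per-band mortality relative risks and projected deaths."""
    return pd.read_csv(_fixture_dir(name) / "mortality_projection.csv")
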