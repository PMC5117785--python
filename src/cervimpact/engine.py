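"""Counterfactual projection of cancers and deaths under screening scenarios.

Given stage-specific case counts N_isj (age band i, stage s, screening
category j) and odds ratios OR_isj versus the never-screened category, the
number of stage-s cancers that would be diagnosed *in the absence of
screening* is estimated by inverse-OR weighting,

    A_is = sum_j N_isj / OR_isj,

and under universal regular screening by A_is * OR_is,regular.  Excess
deaths within 5 years multiply each cell by the age- and stage-specific
case fatality rho_is = 1 - 5-year relative survival; stage-1A cancers in
never-screened women are assigned stage-1B fatality by default, because
microinvasive 1A disease is essentially only found by screening and would
otherwise present later.

Marginal (all-stage) relative risks for a screening category are formed
indirectly: the observed cell sums divided by the corresponding
no-screening sums, with fatality weights for the mortality endpoint.
Their CIs use the delta method on the log RR, treating the counts as fixed
and combining the stage-specific log-OR variances with squared
denominator-share weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tables as T
from .clr import Z95
from .tables import CaseCountTable, FatalityTable, ORCell, ORTable, ObservedDeaths

SCENARIOS = ("current", "no_screening", "all_regular")
FATALITY_RULES = ("substitute_1b", "keep_1a")


@dataclass(frozen=True)
class Scenario:
    name: str = "current"
    fatality_rule_1a: str = "substitute_1b"

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.fatality_rule_1a not in FATALITY_RULES:
            raise ValueError(f"unknown 1A fatality rule {self.fatality_rule_1a!r}")


@dataclass(frozen=True)
class RRWithCI:
    """A relative risk with 95% CI and log-scale variance."""

    rr: float
    lo: float
    hi: float
    var_log: float

    @classmethod
    def from_var(cls, rr: float, var_log: float) -> "RRWithCI":
        half = Z95 * math.sqrt(var_log)
        return cls(rr, rr * math.exp(-half), rr * math.exp(half), var_log)


def _staged_cells(counts: CaseCountTable, band: str):
    for (b, s, c), n in counts.entries.items():
        if b == band and s != T.STAGE_UNKNOWN:
            yield s, c, n


def _require_or(ors: ORTable, band: str, stage: str, category: str) -> ORCell:
    if not ors.has(band, stage, category):
        raise ValueError(f"no OR for occupied cell {(band, stage, category)}")
    cell = ors.get(band, stage, category)
    if cell.odds_ratio == 0.0:
        raise ValueError(f"zero OR in cell {(band, stage, category)}")
    return cell


def counterfactual_cancers(
    counts: CaseCountTable, ors: ORTable, scenario: Scenario | str = "no_screening"
) -> CaseCountTable:
    """Project case counts under a screening scenario.

    ``current`` returns the (staged) counts unchanged; ``no_screening``
    pools each (band, stage) into the never-screened category with value
    sum_j N/OR; ``all_regular`` places sum_j (N/OR) * OR_regular in the
    regular category.  Unknown-stage rows must have been reallocated (or
    deliberately dropped) beforehand and are ignored here.
    """
    name = scenario.name if isinstance(scenario, Scenario) else scenario
    if name == "current":
        return CaseCountTable(
            {k: v for k, v in counts.entries.items() if k[1] != T.STAGE_UNKNOWN}
        )
    out: dict[tuple[str, str, str], float] = {}
    for band in counts.bands():
        absent: dict[str, float] = {}
        for stage, cat, n in _staged_cells(counts, band):
            cell = _require_or(ors, band, stage, cat)
            absent[stage] = absent.get(stage, 0.0) + n / cell.odds_ratio
        for stage, a in absent.items():
            if name == "no_screening":
                out[(band, stage, T.NOT_SCREENED)] = a
            elif name == "all_regular":
                reg = _require_or(ors, band, stage, T.REGULAR)
                out[(band, stage, T.REGULAR)] = a * reg.odds_ratio
            else:
                raise ValueError(f"unknown scenario {name!r}")
    return CaseCountTable(out)


def _rho(fatality: FatalityTable, band: str, stage: str, category: str, rule: str) -> float:
    """Cell fatality, applying the 1A->1B substitution to never-screened 1A."""
    if stage == T.STAGE_1A and category == T.NOT_SCREENED and rule == "substitute_1b":
        return fatality.get(band, T.STAGE_1B)
    return fatality.get(band, stage)


def excess_deaths(
    counts: CaseCountTable, fatality: FatalityTable, scenario: Scenario = Scenario()
) -> dict[str, float]:
    """Excess deaths within 5 years per age band: sum of N_cell * rho_cell.

    ``counts`` must already be the scenario's projected counts (so for
    ``no_screening`` every cell sits in the never-screened category and
    the 1A rule applies throughout).  ``fatality`` must be tabulated on
    the same age bands as ``counts``.
    """
    out: dict[str, float] = {}
    for band in counts.bands():
        total = 0.0
        for stage, cat, n in _staged_cells(counts, band):
            total += n * _rho(fatality, band, stage, cat, scenario.fatality_rule_1a)
        out[band] = total
    return out


def align_fatality(
    fatality: FatalityTable, counts: CaseCountTable, weights: dict[str, float] | None = None
) -> FatalityTable:
    """Collapse a fine-band fatality table onto the count table's bands.

    Published fatality is tabulated on finer age bands than the OR tables
    (e.g. 35-49 and 50-64 separately while ORs pool 35-64); cells are
    averaged per stage, unweighted unless per-fine-band case ``weights``
    are given.
    """
    need = set(counts.bands())
    have = set(fatality.bands())
    if need <= have:
        return fatality
    mapping = {b: srcs for b, srcs in T.SURVIVAL_TO_OR_BANDS.items() if b in need}
    missing = need - set(mapping)
    if missing:
        raise ValueError(f"no fatality data for bands {sorted(missing)}")
    return fatality.collapse(mapping, weights)


def indirect_rr(
    counts: CaseCountTable,
    ors: ORTable,
    fatality: FatalityTable | None,
    endpoint: str,
    category: str,
    band: str,
    fatality_rule_1a: str = "substitute_1b",
) -> RRWithCI:
    """Marginal RR for one screening category versus never screened.

    incidence:  sum_s N_s,cat / sum_s (N_s,cat / OR_s,cat)
    mortality:  the same sums weighted by case fatality -- the numerator
                by the observed cell's fatality, the denominator by
                never-screened fatality with the 1A->1B rule.

    var(log RR) = sum_s w_s^2 se_log(OR_s,cat)^2 with w_s the stage's
    share of the denominator sum (delta method; counts treated as fixed).
    """
    if endpoint not in ("incidence", "mortality"):
        raise ValueError("endpoint must be 'incidence' or 'mortality'")
    if category == T.NOT_SCREENED:
        return RRWithCI(1.0, 1.0, 1.0, 0.0)
    if endpoint == "mortality" and fatality is None:
        raise ValueError("mortality endpoint requires a fatality table")

    num = 0.0
    den_terms: list[tuple[float, float]] = []  # (denominator term, se_log)
    seen = False
    for stage, cat, n in _staged_cells(counts, band):
        if cat != category:
            continue
        seen = True
        cell = _require_or(ors, band, stage, category)
        w_num = 1.0 if endpoint == "incidence" else _rho(fatality, band, stage, category, fatality_rule_1a)
        w_den = (
            1.0
            if endpoint == "incidence"
            else _rho(fatality, band, stage, T.NOT_SCREENED, fatality_rule_1a)
        )
        num += n * w_num
        den_terms.append((n / cell.odds_ratio * w_den, cell.se_log))
    if not seen:
        raise ValueError(f"no cells for category {category!r} in band {band!r}")
    den = sum(t for t, _ in den_terms)
    var_log = sum((t / den) ** 2 * se**2 for t, se in den_terms)
    return RRWithCI.from_var(num / den, var_log)


def scenario_mortality_rr(
    counts: CaseCountTable,
    ors: ORTable,
    fatality: FatalityTable,
    band: str,
    scenario_name: str,
    fatality_rule_1a: str = "substitute_1b",
) -> RRWithCI:
    """RR of 5-year mortality under a scenario versus current screening.

    Deaths under the scenario divided by deaths under current screening
    for one age band.  The delta-method variance combines each cell's
    log-OR variance with the squared sensitivity of the log death total
    (current-screening deaths carry no OR variance since the observed
    counts are treated as fixed).
    """
    scen = Scenario(scenario_name, fatality_rule_1a)
    current = excess_deaths(
        counterfactual_cancers(counts, ors, "current"), fatality, Scenario("current", fatality_rule_1a)
    )[band]
    projected = excess_deaths(counterfactual_cancers(counts, ors, scen), fatality, scen)[band]

    # partial derivatives of ln(projected deaths) w.r.t. each ln OR_sj
    partials: dict[tuple[str, str], float] = {}
    for stage, cat, n in _staged_cells(counts, band):
        cell = _require_or(ors, band, stage, cat)
        rho_ns = _rho(fatality, band, stage, T.NOT_SCREENED, fatality_rule_1a)
        if scenario_name == "no_screening":
            contrib = n / cell.odds_ratio * rho_ns
        else:  # all_regular
            reg = _require_or(ors, band, stage, T.REGULAR)
            rho_reg = _rho(fatality, band, stage, T.REGULAR, fatality_rule_1a)
            contrib = n / cell.odds_ratio * reg.odds_ratio * rho_reg
        if cell.se_log > 0.0:
            key = (stage, cat)
            partials[key] = partials.get(key, 0.0) - contrib / projected
        if scenario_name == "all_regular":
            key = (stage, T.REGULAR)
            partials[key] = partials.get(key, 0.0) + contrib / projected
    var_log = 0.0
    for (stage, cat), d in partials.items():
        se = ors.get(band, stage, cat).se_log
        var_log += d**2 * se**2
    return RRWithCI.from_var(projected / current, var_log)


# ---------------------------------------------------------------------------
# deaths-prevented accounting
# ---------------------------------------------------------------------------


def death_band_label(diagnosis_band: str, shift_years: float = 5.0, floor: float = 25.0) -> str:
    """Age-at-death band for an age-at-diagnosis band.

    Deaths within five years of diagnosis shift both bounds by five years;
    the lowest band's lower bound stays at the screening floor (no deaths
    precede diagnosis, and diagnoses start at 25), so 25-34 at diagnosis
    maps to 25-39 at death and 35-49 to 40-54.
    """
    b = T.AgeBand.from_label(diagnosis_band)
    lower = b.lower + shift_years if b.lower > floor + 0.5 else b.lower
    return T.AgeBand(lower, b.upper + shift_years, role="death").label


@dataclass
class DeathsReport:
    """Absolute annual deaths under each scenario, with the headline shares."""

    per_band: pd.DataFrame
    observed_all_ages: float
    total_no_screening: RRWithCI  # all-ages deaths absent screening, with CI
    total_all_regular: RRWithCI
    additional_no_screening: float
    further_preventable: float
    fraction_currently_prevented: RRWithCI  # share of no-screening deaths prevented now
    fraction_preventable: RRWithCI  # share preventable under universal regular screening


def _total_with_ci(
    rr_by_band: dict[str, RRWithCI], observed: ObservedDeaths, band_map: dict[str, str]
) -> RRWithCI:
    """All-ages deaths total: sum of RR x observed plus the out-of-band remainder."""
    total = observed.out_of_bands()
    var = 0.0
    for diag_band, rr in rr_by_band.items():
        obs = observed.entries[band_map[diag_band]]
        est = rr.rr * obs
        total += est
        var += est**2 * rr.var_log  # Var(RR * O) ~= O^2 RR^2 var_log
    return RRWithCI.from_var(total, var / total**2)


def deaths_prevented(
    rr_by_band: dict[str, dict[str, RRWithCI]],
    observed: ObservedDeaths,
    band_map: dict[str, str] | None = None,
) -> DeathsReport:
    """Convert per-band scenario RRs into absolute annual deaths.

    ``rr_by_band`` maps each diagnosis band to ``{"no_screening": RRWithCI,
    "all_regular": RRWithCI}`` (mortality RRs versus current screening).
    Observed deaths in bands outside the diagnosis range (under 25 / over
    79 at diagnosis) are held constant in every scenario.
    """
    if band_map is None:
        band_map = {b: death_band_label(b) for b in rr_by_band}
    missing = [band_map[b] for b in rr_by_band if band_map[b] not in observed.entries]
    if missing:
        raise ValueError(f"observed deaths missing for death bands {missing}")

    rows = []
    for diag_band, rrs in sorted(rr_by_band.items()):
        obs = observed.entries[band_map[diag_band]]
        rows.append(
            {
                "diagnosis_band": diag_band,
                "death_band": band_map[diag_band],
                "observed": obs,
                "no_screening": rrs["no_screening"].rr * obs,
                "all_regular": rrs["all_regular"].rr * obs,
            }
        )
    per_band = pd.DataFrame(rows)

    tot_ns = _total_with_ci(
        {b: rrs["no_screening"] for b, rrs in rr_by_band.items()}, observed, band_map
    )
    tot_reg = _total_with_ci(
        {b: rrs["all_regular"] for b, rrs in rr_by_band.items()}, observed, band_map
    )
    obs_all = observed.all_ages
    additional = tot_ns.rr - obs_all
    further = obs_all - tot_reg.rr

    # fraction of no-screening deaths prevented: 1 - observed / total_ns.
    # CIs propagate the totals' CIs with observed held fixed.
    def frac(numer_total: RRWithCI, minus: float) -> RRWithCI:
        f = 1.0 - minus / numer_total.rr
        lo = 1.0 - minus / numer_total.lo
        hi = 1.0 - minus / numer_total.hi
        return RRWithCI(f, min(lo, hi), max(lo, hi), numer_total.var_log)

    frac_current = frac(tot_ns, obs_all)
    # preventable share: 1 - total_regular / total_ns; propagate both CIs
    # through the log-ratio variance sum.
    ratio = tot_reg.rr / tot_ns.rr
    var_ratio = tot_reg.var_log + tot_ns.var_log
    half = Z95 * math.sqrt(var_ratio)
    frac_prev = RRWithCI(
        1.0 - ratio,
        1.0 - ratio * math.exp(half),
        1.0 - ratio * math.exp(-half),
        var_ratio,
    )

    return DeathsReport(
        per_band=per_band,
        observed_all_ages=obs_all,
        total_no_screening=tot_ns,
        total_all_regular=tot_reg,
        additional_no_screening=additional,
        further_preventable=further,
        fraction_currently_prevented=frac_current,
        fraction_preventable=frac_prev,
    )


# ---------------------------------------------------------------------------
# bootstrap cross-check for the delta-method CIs
# ---------------------------------------------------------------------------


def bootstrap_rr_ci(
    counts: CaseCountTable,
    ors: ORTable,
    fatality: FatalityTable | None,
    endpoint: str,
    category: str,
    band: str,
    n_reps: int = 10_000,
    seed: int = 0,
    fatality_rule_1a: str = "substitute_1b",
) -> tuple[float, float]:
    """Parametric-bootstrap 95% CI for :func:`indirect_rr`.

    Log ORs are resampled independently from N(ln OR, se_log^2) and the
    indirect combination recomputed; returns the 2.5/97.5 percentiles.
    """
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    base = {
        k: cell for k, cell in ors.entries.items() if k[0] == band
    }
    for r in range(n_reps):
        perturbed = {}
        for (b, s, c), cell in base.items():
            if c == T.NOT_SCREENED:
                perturbed[(b, s, c)] = cell
                continue
            o = math.exp(rng.normal(math.log(cell.odds_ratio), cell.se_log))
            perturbed[(b, s, c)] = ORCell(o, o, o, cell.se_log)
        reps[r] = indirect_rr(
            counts, ORTable(perturbed), fatality, endpoint, category, band, fatality_rule_1a
        ).rr
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)
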