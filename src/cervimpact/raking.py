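"""Survival raking: age-within-stage structure from one source, marginals
from others.

Age- and stage-specific 5-year relative survival is rarely published for
one population, but a reference grid (e.g. SEER) gives the *joint* age x
stage pattern while registry reports give marginal stage-specific and
marginal age-specific survival for the target population.  The raking
procedure reconciles them under proportional excess hazards: applying a
hazard ratio ``h`` to a 5-year relative survival ``s`` yields ``s**h``
(scaling the cumulative excess hazard -ln s).

Pass 1 finds, for each stage, the hazard ratio ``h_s`` such that the
case-weighted survival over age bands matches the target stage marginal;
pass 2 then finds, for each age band, ``h_i`` matching the age marginal.
The second pass perturbs the stage marginals slightly; that is the
documented behaviour of the two-pass procedure, and an optional iterated
mode alternates passes until both sets of marginals hold jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

from .tables import FatalityTable

H_BRACKET = (1e-3, 1e3)
ROOT_TOL = 1e-10


@dataclass
class SurvivalGrid:
    """5-year relative survival s in (0, 1] and case weights per (band, stage)."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, s in self.entries.items():
            if not 0.0 < s <= 1.0:
                raise ValueError(f"survival outside (0, 1] in {key}")
            if self.weights.get(key, 0.0) < 0.0:
                raise ValueError(f"negative weight in {key}")

    def bands(self) -> list[str]:
        return sorted({b for b, _ in self.entries})

    def stages(self) -> list[str]:
        return sorted({s for _, s in self.entries})


def apply_hazard_ratio(s: float, h: float) -> float:
    """Survival after scaling the cumulative excess hazard by ``h``: s**h."""
    if h <= 0.0:
        raise ValueError("hazard ratio must be positive")
    if s == 0.0 and h < 1.0:
        raise ValueError("cannot attenuate a zero survival")
    if not 0.0 <= s <= 1.0:
        raise ValueError("survival must lie in [0, 1]")
    return s**h


def _solve_h(cells, target: float, label: str) -> float:
    """Hazard ratio h with sum_k w_k s_k**h = target (w normalized here)."""
    wsum = sum(w for _, w in cells)
    if wsum <= 0.0:
        raise ValueError(f"{label}: no weight mass")
    if not 0.0 < target < 1.0:
        raise ValueError(f"{label}: marginal target {target} outside (0, 1)")

    def f(h):
        return sum(w * s**h for s, w in cells) / wsum - target

    lo, hi = H_BRACKET
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        raise ValueError(
            f"{label}: marginal target {target} unattainable within "
            f"hazard-ratio bracket {H_BRACKET}"
        )
    return brentq(f, lo, hi, xtol=ROOT_TOL)


def rake_pass(grid: SurvivalGrid, marginals: dict[str, float], axis: str) -> SurvivalGrid:
    """One raking pass matching stage (axis='stage') or age (axis='band') marginals."""
    if axis not in ("stage", "band"):
        raise ValueError("axis must be 'stage' or 'band'")
    out = dict(grid.entries)
    keys = grid.stages() if axis == "stage" else grid.bands()
    for key in keys:
        cells = [
            (s, grid.weights.get((b, st), 0.0))
            for (b, st), s in grid.entries.items()
            if (st if axis == "stage" else b) == key
        ]
        h = _solve_h(cells, marginals[key], f"{axis} {key!r}")
        for cell_key, s in grid.entries.items():
            b, st = cell_key
            if (st if axis == "stage" else b) == key:
                out[cell_key] = s**h
    return SurvivalGrid(out, dict(grid.weights))


def marginal(grid: SurvivalGrid, axis: str) -> dict[str, float]:
    """Case-weighted marginal survival along an axis."""
    keys = grid.stages() if axis == "stage" else grid.bands()
    out = {}
    for key in keys:
        num = den = 0.0
        for (b, st), s in grid.entries.items():
            if (st if axis == "stage" else b) == key:
                w = grid.weights.get((b, st), 0.0)
                num += w * s
                den += w
        out[key] = num / den
    return out


def rake_survival(
    seer_grid: SurvivalGrid,
    stage_marginals: dict[str, float],
    age_marginals: dict[str, float],
    iterate: bool = False,
    max_rounds: int = 100,
    tol: float = 1e-10,
) -> FatalityTable:
    """Rake a reference survival grid to external marginals; return fatality.

    Default behaviour is exactly two passes -- stage, then age -- so the
    final grid honours the age marginals exactly and the stage marginals
    approximately.  With ``iterate=True`` the passes alternate until both
    marginals hold to ``tol``.
    """
    grid = rake_pass(seer_grid, stage_marginals, "stage")
    grid = rake_pass(grid, age_marginals, "band")
    if iterate:
        for _ in range(max_rounds):
            stage_err = max(
                abs(marginal(grid, "stage")[k] - v) for k, v in stage_marginals.items()
            )
            if stage_err < tol:
                break
            grid = rake_pass(grid, stage_marginals, "stage")
            grid = rake_pass(grid, age_marginals, "band")
    return FatalityTable({key: 1.0 - s for key, s in grid.entries.items()})
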