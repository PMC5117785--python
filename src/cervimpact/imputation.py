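"""Reallocation of unknown-stage cases.

Stage 1A cancers are essentially always staged (microinvasive disease is a
histological diagnosis), so unknown-stage cases are assumed not to be 1A
but otherwise missing at random given age.  The default mode therefore
distributes each age band's unknown count over stages 1B, 2 and 3+ in
proportion to the band's known counts of those stages; within a receiving
stage, the allocated mass follows the stage's own screening-category
distribution (the unknowns' screening histories are not available in the
aggregate tables).  Sensitivity variants move the unknowns elsewhere or
not at all.
"""

from __future__ import annotations

from . import tables as T
from .tables import CaseCountTable

MODES = ("proportional_1b_2_3", "none", "all_stage2", "all_stage3", "proportional_all")

_RECEIVERS = {
    "proportional_1b_2_3": (T.STAGE_1B, T.STAGE_2, T.STAGE_3PLUS),
    "all_stage2": (T.STAGE_2,),
    "all_stage3": (T.STAGE_3PLUS,),
    "proportional_all": T.STAGES,
}


def reallocate_missing(counts: CaseCountTable, mode: str = "proportional_1b_2_3") -> CaseCountTable:
    """Distribute unknown-stage counts over receiving stages per band.

    Counts stay fractional; per-band totals are conserved; with the
    default mode stage-1A cells are untouched.  ``mode='none'`` drops the
    unknown rows (the no-reallocation sensitivity analysis uses only the
    staged cases).
    """
    if mode not in MODES:
        raise ValueError(f"unknown reallocation mode {mode!r}; choose from {MODES}")
    out = dict(counts.entries)
    for band in counts.bands():
        unknown = counts.unknown(band)
        out.pop((band, T.STAGE_UNKNOWN, T.ALL_CATEGORIES), None)
        if mode == "none" or unknown == 0.0:
            continue
        receivers = _RECEIVERS[mode]
        stage_totals = {s: counts.stage_total(band, s) for s in receivers}
        pool = sum(stage_totals.values())
        if pool <= 0.0:
            raise ValueError(
                f"band {band}: {unknown:g} unknown-stage cases but no counts "
                f"in receiving stages {receivers}"
            )
        for (b, s, c), n in counts.entries.items():
            if b != band or s not in receivers or s == T.STAGE_UNKNOWN:
                continue
            # stage share of the pool times the cell's share of its stage
            out[(b, s, c)] = n * (1.0 + unknown / pool)
    return CaseCountTable(out)
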