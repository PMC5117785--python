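import pytest
from hypothesis import settings

import cervimpact as cv
from cervimpact import engine, imputation

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_tables():
    """The packaged England-audit aggregate tables."""
    return cv.load_fixture_tables("england_audit")


@pytest.fixture(scope="session")
def imputed(fixture_tables):
    """Counts after default unknown-stage reallocation, with aligned fatality."""
    counts, ors, fatality, observed = fixture_tables
    counts = imputation.reallocate_missing(counts)
    return counts, ors, engine.align_fatality(fatality, counts), observed


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort under the fixture-implied conditions.

    Stage is never blanked so every set contributes to stage-specific fits.
    """
    cfg = cv.SimConfig.from_fixture(n_sets=600, seed=11, missing_stage_fraction=0.0)
    sets = cv.simulate_cohort(cfg)
    women = [w for m in sets for w in m.women]
    smears = {w.woman_id: w.smears for w in women}
    categories = cv.classify_cohort(women, smears)
    return cfg, sets, categories


@pytest.fixture(scope="session")
def large_cohort():
    """The 5000-set cohort used for parameter-recovery checks."""
    cfg = cv.SimConfig.from_fixture(n_sets=5000, seed=7, missing_stage_fraction=0.0)
    sets = cv.simulate_cohort(cfg)
    women = [w for m in sets for w in m.women]
    smears = {w.woman_id: w.smears for w in women}
    categories = cv.classify_cohort(women, smears)
    return cfg, sets, categories
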