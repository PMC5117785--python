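import math

import numpy as np
import pytest

import cervimpact as cv
from cervimpact import clr
from cervimpact import tables as T


def grid_argmax(X, y, groups, grid):
    """Grid-search maximizer of the 1-covariate conditional likelihood."""
    total = np.zeros_like(grid)
    for g in sorted(set(groups)):
        rows = [i for i, gg in enumerate(groups) if gg == g]
        x = np.array([X[i][0] for i in rows])
        case = x[[y[i] for i in rows].index(1)]
        etas = np.outer(x, grid)
        total += case * grid - np.logaddexp.reduce(etas, axis=0)
    return grid[int(np.argmax(total))]


def brute_loglik(beta, X, y, groups):
    """Independent evaluation of the conditional likelihood, set by set."""
    total = 0.0
    for g in sorted(set(groups)):
        rows = [i for i, gg in enumerate(groups) if gg == g]
        etas = [sum(b * x for b, x in zip(beta, X[i])) for i in rows]
        case = [i for i in rows if y[i] == 1]
        assert len(case) == 1
        num = math.exp(sum(b * x for b, x in zip(beta, X[case[0]])))
        total += math.log(num / sum(math.exp(e) for e in etas))
    return total


class TestConditionalLoglik:
    def test_uniform_beta_zero_gives_minus_n_log_setsize(self):
        X = [[0.0], [1.0], [0.0]] * 4
        y = [1, 0, 0] * 4
        groups = [i // 3 for i in range(12)]
        assert cv.conditional_loglik([0.0], X, y, groups) == pytest.approx(-4 * math.log(3))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_sets = int(rng.integers(1, 5))
            X, y, groups = [], [], []
            for g in range(n_sets):
                size = int(rng.integers(2, 4))
                for m in range(size):
                    X.append([float(rng.integers(0, 2)), rng.normal()])
                    y.append(1 if m == 0 else 0)
                    groups.append(g)
            beta = rng.normal(size=2)
            assert cv.conditional_loglik(beta, X, y, groups) == pytest.approx(
                brute_loglik(beta, X, y, groups), rel=1e-12
            )

    def test_set_without_case_is_structural_error(self):
        with pytest.raises(ValueError, match="exactly one case"):
            cv.conditional_loglik([0.0], [[1.0], [0.0]], [0, 0], [1, 1])


class TestFitClr:
    def test_symmetric_sets_force_or_one(self):
        # case exposed with controls {1 exposed, 1 unexposed}, and the
        # mirror image: by symmetry the conditional MLE is beta = 0
        X = [[1], [1], [0], [0], [1], [0]]
        y = [1, 0, 0, 1, 0, 0]
        groups = [0, 0, 0, 1, 1, 1]
        fit = cv.fit_clr(X, y, groups, labels=("exposed",))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.or_cells()["exposed"].odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_two_set_instance_matches_hand_mle(self):
        # sets: (case exposed; controls unexposed, unexposed) twice, plus
        # (case unexposed; controls exposed, unexposed).  Conditional
        # likelihood L(b) = [e^b/(e^b+2)]^2 * [1/(e^b+2)]; the score
        # 2 - 3 e^b/(e^b+2) = 0 gives e^b = 4 exactly.
        X = [[1], [0], [0], [1], [0], [0], [0], [1], [0]]
        y = [1, 0, 0, 1, 0, 0, 1, 0, 0]
        groups = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        fit = cv.fit_clr(X, y, groups)
        assert fit.beta[0] == pytest.approx(math.log(4.0), abs=1e-8)

    def test_agrees_with_grid_search_on_ten_sets(self):
        rng = np.random.default_rng(17)
        X, y, groups = [], [], []
        for g in range(10):
            for m in range(3):
                X.append([float(rng.integers(0, 2))])
                y.append(1 if m == 0 else 0)
                groups.append(g)
        fit = cv.fit_clr(X, y, groups)
        assert fit.beta[0] == pytest.approx(
            grid_argmax(X, y, groups, np.arange(-3.0, 3.0, 1e-4)), abs=1e-3
        )

    def test_gradient_vanishes_and_newton_is_monotone(self, small_cohort):
        _, sets, categories = small_cohort
        subset = [m for m in sets if clr._band_of_case(m) == "35-64"][:200]
        X, y, groups, levels = clr.design_matrix(subset, categories)
        fit = cv.fit_clr(X, y, groups, labels=levels)
        assert fit.converged
        blocks = clr._group_blocks(X, y, groups)
        _, grad, _ = clr._loglik_parts(fit.beta, blocks)
        assert np.max(np.abs(grad)) < 1e-6

    def test_complete_separation_is_flagged(self):
        # exposure perfectly predicts case status across all sets
        X = [[1], [0], [0]] * 4
        y = [1, 0, 0] * 4
        groups = [i // 3 for i in range(12)]
        fit = cv.fit_clr(X, y, groups)
        assert not fit.converged
        assert fit.beta[0] > 0  # direction of divergence is reported

    def test_no_informative_sets_is_an_error(self):
        X = [[1], [1], [1], [0], [0], [0]]
        y = [1, 0, 0, 1, 0, 0]
        groups = [0, 0, 0, 1, 1, 1]
        with pytest.raises(ValueError, match="informative"):
            cv.fit_clr(X, y, groups)

    def test_cross_check_against_statsmodels(self, small_cohort):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        _, sets, categories = small_cohort
        subset = [m for m in sets if clr._band_of_case(m) == "35-64"]
        X, y, groups, levels = clr.design_matrix(subset, categories)
        fit = cv.fit_clr(X, y, groups, labels=levels)
        sm = ConditionalLogit(np.asarray(y), np.asarray(X), groups=np.asarray(groups)).fit(
            method="newton", disp=0
        )
        np.testing.assert_allclose(fit.beta, sm.params, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(fit.se, sm.bse, rtol=1e-4, atol=1e-6)

    def test_estimator_params_round_trip(self):
        est = cv.ConditionalLogisticRegression(max_iter=30)
        assert est.get_params()["max_iter"] == 30
        est.set_params(tol_grad=1e-6)
        assert est.tol_grad == 1e-6
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestStageSpecificOrs:
    def test_trend_model_uses_single_ordinal_score(self, small_cohort):
        _, sets, categories = small_cohort
        subset = [m for m in sets if clr._band_of_case(m) == "35-64"][:300]
        X, y, groups, labels = clr.design_matrix(subset, categories, model="trend")
        assert X.shape[1] == 1 and labels == ("trend",)
        fit = cv.fit_clr(X, y, groups, labels=labels)
        assert fit.converged
        assert fit.beta[0] < 0  # screening is protective, so the trend is negative

    def test_table_has_referents_and_cis_bracket(self, small_cohort):
        _, sets, categories = small_cohort
        table = cv.stage_specific_ors(sets, categories)
        assert table.entries, "no strata converged"
        for (band, stage, cat), cell in table.entries.items():
            assert cell.lo <= cell.odds_ratio <= cell.hi
            if cat == T.NOT_SCREENED:
                assert cell.odds_ratio == 1.0

    def test_case_with_missing_stage_record_is_error(self, small_cohort):
        _, sets, _ = small_cohort
        broken = [
            cv.MatchedSet(
                9_999_999,
                tuple(
                    w.__class__(**{**w.__dict__, "stage": None})
                    if w.is_case
                    else w
                    for w in sets[0].women
                ),
            )
        ]
        with pytest.raises(ValueError, match="without a stage"):
            cv.stage_specific_ors(broken, {})
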