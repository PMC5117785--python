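"""Conditional logistic regression for individually matched sets.

For a matched set with members m = 1..M (exactly one case) and covariate
rows x_m, the conditional likelihood contribution is

    P(case | set) = exp(x_case . beta) / sum_m exp(x_m . beta),

which eliminates the per-set nuisance intercepts that age-and-area matching
induces.  The total conditional log-likelihood is concave, so Newton-
Raphson from the origin with step-halving converges whenever the MLE is
finite; complete separation (a category appearing only in cases or only in
controls) drives a coefficient to infinity and is flagged rather than
"solved".

The public entry points are a small scikit-learn-style estimator,
:class:`ConditionalLogisticRegression`, functional wrappers
(:func:`conditional_loglik`, :func:`fit_clr`), and
:func:`stage_specific_ors`, which fits one model per (age band, FIGO
stage) stratum of a classified cohort and assembles the OR table the
counterfactual projection consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import tables as T
from .tables import ORCell, ORTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _group_blocks(X, y, groups):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    if X.ndim != 2 or len(y) != len(X) or len(groups) != len(X):
        raise ValueError("X, y, groups must have matching first dimensions")
    blocks = []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        cases = np.flatnonzero(y[idx] == 1)
        if len(cases) != 1:
            raise ValueError(f"matched set {g!r} must contain exactly one case")
        blocks.append((X[idx], int(cases[0])))
    return blocks


def _loglik_parts(beta, blocks, want_derivs=True):
    ll = 0.0
    p = len(beta)
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for Xg, ci in blocks:
        eta = Xg @ beta
        lse = logsumexp(eta)
        ll += eta[ci] - lse
        if want_derivs:
            w = np.exp(eta - lse)
            xbar = w @ Xg
            grad += Xg[ci] - xbar
            hess -= (Xg.T * w) @ Xg - np.outer(xbar, xbar)
    return ll, grad, hess


def conditional_loglik(beta, X, y, groups) -> float:
    """Conditional log-likelihood sum_sets [x_case.beta - ln sum_m exp(x_m.beta)]."""
    blocks = _group_blocks(X, y, groups)
    return _loglik_parts(np.asarray(beta, dtype=float), blocks, want_derivs=False)[0]


@dataclass
class FitResult:
    """Fitted log-odds-ratios with their covariance.

    ``labels`` names the covariate columns; ``converged`` is False under
    complete separation, in which case ``beta`` holds the diverging
    direction (signs are meaningful, magnitudes are not).
    """

    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    loglik: float
    n_iter: int
    labels: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def or_cells(self) -> dict[str, ORCell]:
        """Wald 95% cells exp(beta +/- 1.96 se), keyed by covariate label."""
        out = {}
        for j, label in enumerate(self.labels):
            b, s = self.beta[j], self.se[j]
            out[label] = ORCell(
                float(np.exp(b)), float(np.exp(b - Z95 * s)), float(np.exp(b + Z95 * s)), float(s)
            )
        return out


class ConditionalLogisticRegression:
    """Newton-Raphson conditional logistic regression (1:M matching).

    Parameters
    ----------
    max_iter : int
        Newton iteration cap.
    tol_loglik, tol_grad : float
        Convergence when the log-likelihood improves by less than
        ``tol_loglik`` or the gradient max-norm falls below ``tol_grad``.
    separation_bound : float
        A coefficient exceeding this magnitude with a non-vanishing
        gradient is treated as diverging (complete separation).

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) log odds ratios
    cov_ : (p, p) inverse observed information
    converged_, loglik_, n_iter_
    """

    def __init__(self, max_iter=50, tol_loglik=1e-10, tol_grad=1e-8, separation_bound=15.0):
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_grad = tol_grad
        self.separation_bound = separation_bound

    # minimal sklearn-compatible parameter plumbing
    def get_params(self, deep=True):
        return {
            "max_iter": self.max_iter,
            "tol_loglik": self.tol_loglik,
            "tol_grad": self.tol_grad,
            "separation_bound": self.separation_bound,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, groups):
        blocks = _group_blocks(X, y, groups)
        informative = [
            (Xg, ci) for Xg, ci in blocks if not np.allclose(Xg, Xg[0], atol=0.0)
        ]
        if not informative:
            raise ValueError("no informative sets: covariates are constant within every set")
        p = np.asarray(X, dtype=float).shape[1]
        beta = np.zeros(p)
        ll, grad, hess = _loglik_parts(beta, informative)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step-halving keeps the iterates monotone in log-likelihood
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new = _loglik_parts(cand, informative, want_derivs=False)[0]
                if ll_new >= ll:
                    break
                scale *= 0.5
            beta = beta + scale * step
            ll_prev, ll = ll, ll_new
            _, grad, hess = _loglik_parts(beta, informative)
            if np.max(np.abs(grad)) < self.tol_grad or abs(ll - ll_prev) < self.tol_loglik:
                converged = True
                break
        if np.max(np.abs(beta)) >= self.separation_bound:
            converged = False
        info = -hess
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        self.coef_ = beta
        self.cov_ = cov
        self.converged_ = bool(converged)
        self.loglik_ = float(ll)
        self.n_iter_ = it
        return self


def fit_clr(X, y, groups, labels=(), **params) -> FitResult:
    """Fit a conditional logistic regression; see the estimator class."""
    est = ConditionalLogisticRegression(**params).fit(X, y, groups)
    return FitResult(
        beta=est.coef_,
        cov=est.cov_,
        converged=est.converged_,
        loglik=est.loglik_,
        n_iter=est.n_iter_,
        labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# cohort-level model matrices
# ---------------------------------------------------------------------------


def _band_of_case(mset) -> str:
    case = mset.case
    age = (case.reference_date - case.birth_date).days / T.YEAR_DAYS
    # the widened-inclusion sensitivity admits 24.5-25.5-year-olds, who
    # pool into the youngest tabulated band
    return T.band_for_age(max(age, 25.5))


def design_matrix(sets, categories, model="categorical", levels=None):
    """Model matrix for a list of matched sets.

    ``categories`` maps woman_id to a screening category (or to a
    ``(category, interval)`` pair as produced by the classifier).  The
    categorical model uses indicator columns for each non-referent level
    (ascending regularity); the trend model uses the single ordinal score.
    """

    def cat_of(w):
        c = categories[w.woman_id]
        return c[0] if isinstance(c, tuple) else c

    if model not in ("categorical", "trend"):
        raise ValueError("model must be 'categorical' or 'trend'")
    if model == "categorical":
        if levels is None:
            present = {cat_of(w) for mset in sets for w in mset.women}
            levels = [
                c for c in T.CATEGORIES if c in present and c != T.NOT_SCREENED
            ]
        rows, y, groups = [], [], []
        for mset in sets:
            for w in mset.women:
                c = cat_of(w)
                rows.append([1.0 if c == lev else 0.0 for lev in levels])
                y.append(int(w.is_case))
                groups.append(mset.set_id)
        return np.array(rows), np.array(y), np.array(groups), tuple(levels)
    rows, y, groups = [], [], []
    for mset in sets:
        for w in mset.women:
            rows.append([float(T.CATEGORY_SCORE[cat_of(w)])])
            y.append(int(w.is_case))
            groups.append(mset.set_id)
    return np.array(rows), np.array(y), np.array(groups), ("trend",)


def stage_specific_ors(sets, categories, include_unknown=False) -> ORTable:
    """Fit one conditional model per (age band, case stage) stratum.

    Each stratum uses the sets whose *case* carries that band and stage;
    the case's controls are retained regardless of their own (null) stage.
    Strata that are empty or fail to converge leave their cells absent.
    """
    strata: dict[tuple[str, str], list] = {}
    for mset in sets:
        stage = mset.case.stage
        if stage is None:
            raise ValueError(f"set {mset.set_id} has a case without a stage record")
        if stage == T.STAGE_UNKNOWN and not include_unknown:
            continue
        strata.setdefault((_band_of_case(mset), stage), []).append(mset)

    entries: dict[tuple[str, str, str], ORCell] = {}
    for (band, stage), members in sorted(strata.items()):
        X, y, groups, levels = design_matrix(members, categories)
        if not levels:
            continue
        try:
            fit = fit_clr(X, y, groups, labels=levels)
        except ValueError:
            continue
        if not fit.converged:
            continue
        entries[(band, stage, T.NOT_SCREENED)] = T.REFERENT_CELL
        entries.update(
            {(band, stage, lab): cell for lab, cell in fit.or_cells().items()}
        )
    return ORTable(entries)


def marginal_ors(sets, categories, band) -> dict[str, ORCell]:
    """Direct all-stage ORs for one age band (the stage-blind comparator)."""
    subset = [m for m in sets if _band_of_case(m) == band]
    if not subset:
        raise ValueError(f"no sets with a case in band {band}")
    X, y, groups, levels = design_matrix(subset, categories)
    fit = fit_clr(X, y, groups, labels=levels)
    return fit.or_cells()
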