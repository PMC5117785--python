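# Methods

## The estimand and the data

The package estimates what cervical cancer incidence and 5-year mortality
would be under three screening regimes — the current mix, no screening at
all, and universal regular screening — from two kinds of input:

* individual-level matched case-control sets with dated smear records
  (each case age-matched to one or two cancer-free controls, controls
  inheriting the case's diagnosis date as their reference date);
* aggregate tables: case counts `N_isj` and odds ratios `OR_isj` by age
  band `i`, FIGO stage `s` and screening category `j`, a case-fatality
  table `ρ_is`, and observed annual deaths by age band at death.

The real audit records are confidential, so the packaged `england_audit`
fixture carries only the published aggregates, and a synthetic-cohort
generator provides individual-level data with known truth.

## Screening-history classification

A woman's maximum screening interval is the longest period within her
screening window containing no adequate smear. Both boundary gaps count:
without them a single smear 14 years before diagnosis would pass as
regular. Windows: 15 years before diagnosis at ages 35–64 (12- and 8-year
sensitivity variants), ages 50–64 for women 65+, and 3-year age slices
from age 22.5 for women under 35, whose category is attendance-per-slice
rather than interval-based. Cut-offs (3.5 y regular under 50, 5.5 y from
50; 7.5 y irregular; 13 y very irregular) are closed on the regular side,
so a tie resolves toward the better category. Date arithmetic uses
365.25-day years on day-granular dates, which puts interval computations
within ~0.006 y of their nominal values; all category boundaries sit at
least 0.1 y from the generator's target gaps, so day rounding can never
flip a category. A woman with no adequate smear in her window is "not
screened" even when a shortened sensitivity window is itself shorter than
the 13-year cut-off. Women under 25.5 at diagnosis are excluded (the
prevalent-screen peak at 25 is mostly stage 1A and distorts the
incidence association); `min_age=24.5` re-admits them for the
sensitivity analysis, pooled into the youngest band.

## Conditional logistic regression

For set `g` with covariate rows `x_m` and one case, the conditional
log-likelihood is `Σ_g [x_case·β − ln Σ_m exp(x_m·β)]`; sets whose
members share identical covariates contribute a constant and are dropped
before fitting. The likelihood is concave; Newton–Raphson starts at
`β = 0` with step-halving on any decrease, and stops when the
log-likelihood improves by less than 1e-10 or the gradient max-norm falls
below 1e-8 (cap 50 iterations). Complete separation is reported
(`converged = False`, the diverging direction preserved), never papered
over. The covariance is the inverse observed information; CIs are Wald,
`exp(β ± 1.96·se)`, because the downstream delta-method combination
consumes the log-scale SE and the published CI widths are Wald-like.
Stage-specific tables fit one model per (band, case stage) stratum with
indicator covariates per non-referent category; the trend model replaces
them with the single ordinal score 0–3 (integer scores; the alternative
of interval midpoints is not used). The published ORs' log-scale SEs are
reconstructed from their CIs as `(ln hi − ln lo)/(2·1.96)`.

## Missing-stage reallocation

Stage 1A is assumed always recorded, so unknown-stage cases are assumed
missing at random among stages 1B/2/3+ conditional on age: each band's
unknown count scales the band's 1B/2/3+ cells by a common factor
`1 + U_i / (K_1B + K_2 + K_3)`. Splitting within a stage proportionally
to the stage's own category distribution is a neutral approximation — the
aggregate tables do not carry the unknowns' screening histories. Counts
stay fractional throughout (the projections are linear in `N`). Variants:
no reallocation, all to stage 2, all to stage 3+, proportional over all
four stages. The published aggregate tables do not give the unknowns' age
distribution either; the fixture loader splits the 1579 unknown-stage
cases across bands proportionally to staged cases.

The loader also normalizes each stage's printed category percentages by
their printed sum (99.9–100.1 due to rounding) so that per-stage counts
add exactly to the stage's printed `n`; this changes cells by ≤0.1% and
the headline RRs by <0.001, and makes the total-count invariants exact.

## Survival raking

"Applying a hazard ratio `h` to survival `s`" means `s^h` — scaling the
cumulative excess hazard `−ln s`, the standard actuarial identity for
relative survival. Pass 1 finds, per stage, the `h_s` (Brent's method on
`h ∈ [1e-3, 1e3]`, tolerance 1e-10; the marginal is monotone in `h`, so a
sign change over the bracket certifies attainability) matching the
case-weighted stage marginal; pass 2 does the same per age band. The
default is exactly two passes in that order, which honours the age
marginals exactly and perturbs the stage marginals slightly — this
mirrors the narrative order of the original procedure and is documented
rather than "fixed". An `iterate=True` mode alternates passes; it
converges geometrically when the two marginal sets are jointly attainable
by separable per-stage/per-band exponents, and stalls at a compromise
otherwise (the passes then cycle with each undoing a fixed amount of the
other — a limitation of exponent raking that plain IPF on counts does not
share). Marginalization weights default to case counts. The actual
reference age×stage survival inputs behind the packaged fatality table
are not published, so that table ships as data and the raking algorithm
is validated on synthetic grids plus a self-consistency check (seeding
the raking with the packaged table reproduces it).

## Counterfactual projection and indirect RRs

Cancers absent screening: `A_is = Σ_j N_isj / OR_isj` (each screened
cell inflated back to its never-screened equivalent); under universal
regular screening `A_is · OR_is,regular`. Excess deaths within 5 years
multiply each cell by `ρ_is = 1 −` 5-year relative survival, naively
equated with the probability of dying of the cancer within 5 years; this
ignores cause-specific/relative-survival divergence and deaths beyond 5
years. Never-screened stage-1A cells take stage-1B fatality in every
scenario (microinvasive 1A disease is essentially only screen-detected,
so in never-screened women it would have presented later); `keep_1a`
relaxes this for sensitivity.

The marginal RR for category `j` versus never screened is indirect:
`Σ_s N_sj / Σ_s N_sj/OR_sj` for incidence, both sums fatality-weighted
for mortality (numerator by the observed cell's `ρ`, denominator by
never-screened `ρ` with the 1A→1B rule). Treating counts as fixed, the
delta method gives `var(ln RR) = Σ_s w_s² se_s²` with `w_s` the stage's
denominator share; a parametric bootstrap over the log ORs cross-checks
the CI endpoints. Because the published fatality table is finer than the
OR bands, the 35–64 fatality is the unweighted mean of the 35–49 and
50–64 rows per stage (65–79 likewise from 65–69/70–79) unless per-
sub-band weights are configured; the published analysis worked at finer
granularity not recoverable from the aggregate tables, which is the main
source of the small (<0.01) differences from the printed marginal RRs.

Deaths accounting: per diagnosis band, the scenario mortality RR (deaths
under scenario / deaths under current screening) multiplies the observed
annual deaths in the corresponding age-at-death band — both bounds
shifted by 5 years, the lowest band's floor kept at 25. Deaths from
cancers diagnosed under 25 or over 79 are held constant in every
scenario (screening at 25–64 cannot prevent them); the published in-band
total is carried explicitly because the per-band annual averages round to
a sum one higher. Summed totals get CIs from the appropriately weighted
combination of per-band variances.

## The synthetic cohort

Defaults are derived from the packaged fixture so the generator emulates
the target study: age-band weights proportional to staged cases; true
ORs equal to the published stage-specific ORs; control category
prevalence per band implied by the case distribution under the tilting
model (`prev_j ∝ Σ_s N_sj/OR_sj`); baseline stage distribution
proportional to never-screened case counts; missing-stage fraction
1579/11619; single-control sets 1% (the source says only "very
occasionally"; this is a free parameter). Cases draw `(stage, category)`
with probability `∝ π_s · prev_j · OR_sj`, which makes the within-set
conditional OR of category `j` versus never screened exactly `OR_sj`.
Smear dates are then constructed to realize the drawn category: a
designated maximum gap drawn safely inside the category's interval range
(margin 0.1 y against day rounding), remaining gaps at 40–90% of it; for
under-35s one smear per required (or deliberately omitted) age slice.
Inadequate smears are sprinkled in to exercise the adequacy filter. The
generator does not model area-of-residence matching (no estimator uses
it), HPV status, hysterectomy exclusion, participation bias, or any
dependence of smear timing on future case status beyond the category
itself — so passing closed-loop tests demonstrates correctness of the
classification/estimation machinery, not robustness to the messiness of
real call/recall records (transcription errors, migration, private
smears missing from the registry).

## Problem sizes and numerical choices

Parameter-recovery and equivalence checks use 5 000 matched sets, enough
to hold 3-SE bounds comfortably for the 35–64 band cells they assert;
the bootstrap cross-check uses 10 000 replicates. Root-finding and
convergence tolerances are stated above; ties, degenerate inputs
(empty strata, sets without covariate variation, unknown-stage rows
reaching the engine) raise explicit errors rather than guessing.

## Known limitations

* Aggregate-fixture granularity: printed ORs pool 35–64, so the per-band
  published mortality RR rows (4.13, 5.30, …) that used unpublished
  sub-band fits are reproduced only approximately by the pipeline.
* The OR-to-RR step treats case-control ORs as incidence rate ratios and
  the observed associations as causal; self-selection of healthier women
  into screening is not corrected.
* 5-year excess mortality proxies cause-specific mortality; survival is
  assumed independent of detection route within stage.
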