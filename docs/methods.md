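# Methods

## Model overview

The package projects the burden and direct healthcare costs of six
obesity-related conditions in an adult (20+) population over a
2010–2030 horizon, in two stages: (1) a constrained categorical
regression of BMI-category proportions on calendar year, and (2) an
annual-step individual-level simulation of BMI, disease incidence,
survival and death, with intervention scenarios and cost accounting.
All stages exchange plain CSV tables, and all randomness flows from a
single integer seed through named, independent RNG streams.

## Stage 1: categorical BMI trend regression

The published description of this model class specifies a non-linear
multivariate regression with proportions constrained to total 100%, but
not the functional form. We use the standard categorical trend model that
satisfies the constraint by construction: a three-category multinomial
logit, linear in calendar year with additive age-group offsets, fitted
per sex. The likelihood is the multinomial likelihood of effective
counts (proportion × cell n), so surveys are weighted by sample size; a
flag disables weighting, since it is not documented whether the original
model weighted surveys. Age enters as fixed offsets rather than an
age×year interaction for identifiability on sparse survey series
(five survey years in the bundled preset); the interaction is available
behind a flag. Years are centred at the mean survey year for
conditioning.

The fit maximises the (convex) multinomial log-likelihood by trust-region
Newton iteration with analytic gradient and Hessian; the coefficient
covariance is the inverse observed information. The likelihood was
written directly because the widely used multinomial-logit
implementations in the Python ecosystem fit individual-level responses
and do not accept grouped frequency-weighted cells; the fit is verified
in the test suite against an independently coded likelihood maximised by
derivative-free search.

**Outlier rule.** Survey points outside 95% confidence limits are
removed. The reference distribution for those limits is not further
specified in the source description, so the rule is operationalised as
leave-pattern-in prediction limits from a preliminary fit: an
observation's variance is the delta-method variance of its fitted
proportion plus the binomial sampling variance p(1−p)/n, and
observations with |z| > 1.96 are flagged. Whole cells containing a
flagged observation are dropped so that kept cells keep complete
category triples, and the filter is applied exactly once
(filter → refit); iterating to convergence can empty sparse strata.

**Confidence limits.** Bands are a parametric bootstrap: coefficient
vectors drawn from N(β̂, Σ̂), each re-projected, per-cell 2.5/97.5
percentiles taken. This respects the [0,1] scale where the delta method
does not, and bands widen automatically with distance from the data
centroid. Default 500 draws; below 200 a warning is logged.

## Epidemiological input preparation

Remission is fixed at zero for all six conditions (chronic diseases;
the model tracks contracting, surviving and dying only). The
illness–death system S′ = −(i+m)S, C′ = iS − (m+f)C is advanced in
annual age steps using the exact 2×2 matrix exponential of the
piecewise-constant system, so constant-hazard cases are reproduced to
machine precision and step refinement (a monthly option exists) changes
nothing beyond the piecewise-constant approximation itself. Prevalence
inputs are inverted age-by-age: the unique non-negative i(a) whose
one-step forward projection matches the next observed prevalence is
found by bracketed root-finding (tolerance 1e-14); declines that no
non-negative incidence can explain are clamped to i = 0 and the ages
logged. The forward∘inverse round trip is the identity to well under
1e-6 on feasible schedules.

n-year survival s becomes a constant excess hazard f = −ln(s)/n. Case
fatality for the pooled obesity-related cancers is a single excess
hazard; per-site splitting is out of scope. Population incidence is
split by BMI category with i_ref = i_pop / Σₖ pₖRRₖ and iₖ = RRₖ·i_ref,
using the baseline year's projected category proportions per (sex, age),
which preserves the population mixture identity exactly. Initial
prevalence at age 20 defaults to zero for the prevalence→incidence
conversion (configurable); the inversion otherwise starts from the
observed prevalence at the youngest age.

## Stage 2: microsimulation

Each person carries sex, birth year, and a lifelong uniform rank in
(0,1). Every simulated year the rank is mapped through the current
(year, sex, age-group) category distribution, which realises the
assumption that an individual's BMI standing within their cohort is
consistent over time: as the projected obesity proportion rises, a fixed
rank can only move normal → overweight → obese, never backwards (within
a stratum trajectory with a monotone trend). A continuous latent BMI is
the rank's quantile under a per-stratum log-normal whose μ and σ are
solved in closed form so that P(BMI<25) and P(BMI<30) equal the
projected proportions; the continuous scale exists so that percentage
BMI reductions are well defined, and the category implied by the
continuous value is identical to the rank-interval category by
construction.

Time is discrete-annual; hazards become probabilities via 1 − exp(−h).
Event order within a year is BMI update → incidence → disease death →
other-cause death (a fixed constant; the ordering sensitivity is
second-order in the hazards). Diseases evolve conditionally
independently given BMI category. Fatal diseases (CHD & stroke,
cancers) apply their excess hazard to prevalent cases; all persons face
all-cause mortality. The disease stock at the start year is seeded by
Bernoulli draws against the age/sex prevalence implied by each
disease's illness–death schedule, so prevalence (and costs) start from
a realistic base rather than accumulating from zero; cumulative
incidence counts only onsets from the start year onward, whether or not
the case later dies. New entrants at the minimum age keep the age
structure stationary (off by a flag); population counts are allocated
to simulated persons by largest-remainder rounding.

**Common random numbers.** Every draw comes from an RNG stream keyed by
(seed, year, purpose) and is made for every person slot whether or not
the event can apply, so counterfactual scenarios under the same seed
consume identical randomness. A person's incidence and death history
under the 5% scenario is then a per-person coupled counterpart of the
unabated run, which makes cases-avoided differences low-variance and
scenario dominance hold sample-path-wise while persons remain alive in
both runs. Dominance of cumulative incidence is not a strict theorem —
a person dying earlier in the unabated run can in principle accrue a
case only in the intervention run — but this requires a differential
fatal-disease death followed by a later contraction, a second-order
event that the test suite confirms never outweighs the first-order
avoided cases at the default conditions.

**Run size.** The original application reports five million Monte Carlo
runs without defining the unit; we interpret runs as simulated
individuals and default to 100,000 persons per scenario, with replicate
seeds available for uncertainty; per-100,000 outputs converge as 1/√n
(verified in the suite). The session's full pipeline at the default
size completes in well under a minute per scenario.

## Scenarios, attribution, costing

"Population BMI decreases by x%" is read as a multiplicative shift of
each individual's continuous BMI from the scenario start year onward,
with the category re-derived from the WHO cut-offs; a shift of category
proportions instead would be ill-defined without the continuous scale.
All simulation inputs are total-population figures; outputs are
converted to obesity-related figures with the Levin population
attributable fraction computed per (disease, sex, age group, year) from
the realized alive category proportions, reference category normal
weight. Costing is prevalence-based — each obesity-related prevalent
case-year accrues the disease's annual unit cost — the simplest model
consistent with year-by-year cost tables; first-year cost premiums are
not modelled, and costs are undiscounted by default (a discount-rate
knob exists). Indirect costs are extrapolated by scaling direct costs
with the published national ratio (defaults €729m indirect : €399m
direct). Report tables round to three significant figures; full
precision is kept internally.

## Synthetic data: what it emulates, and what it does not

The generator's truth model is the same family stage 1 fits (multinomial
logit in year with age-group offsets), with observed proportions drawn as
multinomial counts at the cell sample size — so stage-1 parameter
recovery, coverage and the outlier rule are all testable against known
truth. The bundled preset mimics the national inputs the original
application drew on: five sparse survey years (1998–2011) of ~1,000
respondents per (year, sex, age-group) cell, a rising obesity trend
calibrated so overweight+obesity reaches the high-80s% (men) and
mid-80s% (women) by 2030 with obesity higher in women, an adult
population of ~3.3M with Gompertz all-cause mortality, and five disease
groups (CHD & stroke pooled, cancers pooled) with plausible incidence or
prevalence schedules, relative risks, five-year survival for the fatal
groups, and annual unit costs in euro.

It does not emulate: self-report vs measured BMI bias, survey design
effects or non-response, secular trends in disease risk or treatment
independent of BMI, migration, or correlations between diseases beyond
shared BMI. Passing tests therefore demonstrate that the pipeline's
statistics and simulation are correct under the stated model, not that
the preset's absolute numbers describe any real population; with real
survey, epidemiology and cost tables in the same CSV schemas, the same
code produces the real-data analysis.

## Numerical choices and degenerate inputs

- Proportions are clipped to [1e-9, 1−1e-9] only when solving the latent
  log-normal (degenerate strata); projections themselves never need
  clipping because of the softmax link.
- Latent BMI is clipped to [5, 1000] kg/m², far outside the cut-offs,
  purely to avoid overflow at degenerate ranks.
- Root brackets for the prevalence inversion expand geometrically to
  i ≤ 1000/yr before declaring infeasibility.
- Ages beyond the oldest age group are clamped into it (open-ended old
  age); hazard schedules clamp to the ends of their support.
- Separation (a category absent from all cells of a sex) aborts the fit
  with the stratum named; an outlier pass that leaves fewer than two
  survey years for a sex aborts rather than silently fitting a line
  through one point.
- Zero-n survey cells are dropped before fitting (they carry no
  likelihood weight and would otherwise perturb year centring).

## Known limitations

Childhood obesity is out of scope (as in the original application), so
entrant BMI at age 20 follows the projected adult distribution. The
attribution step uses current-year category proportions, i.e. no lag
between BMI change and risk change. Disease interactions, intervention
delivery costs, and bottom-up cost decomposition are not modelled. The
outlier rule and survey weighting are one defensible reading of an
under-specified description; both are behind flags.
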