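# Methods

## The decision problem

A healthcare programme is worth funding when the health it generates exceeds
the health forgone elsewhere because its cost displaces other spending. With
an opportunity-cost threshold λ_service (US$ per DALY), a programme averting
d DALYs at additional cost c has net health effect d − c/λ_service DALYs.
Research on an uncertain endpoint X is valuable only insofar as learning X
could change the implementation decision; its value is measured in the same
currency, net DALYs averted.

## Priors

Uncertainty about the endpoint is a parametric prior chosen by family and
fitted by **moment matching** to a stated mean m and standard error s:

* beta on [0, 1]: ν = m(1−m)/s² − 1, shape1 = mν, shape2 = (1−m)ν,
  feasible iff s² < m(1−m);
* normal: (m, s); gamma: shape m²/s², scale s²/m; lognormal:
  σ² = ln(1+s²/m²), μ = ln m − σ²/2; uniform: m ± √3·s.

Moment matching is the primary route because published summaries state a
mean and SE and present any credible interval as a consequence of the prior;
achieved quantiles are therefore reported as diagnostics, never enforced.
(For the beta prior with m = 0.10, s = 0.04 the achieved 95% interval is
(0.036, 0.191), i.e. (0.04, 0.19) at two decimals.) A secondary route,
`fit_prior_from_quantiles`, numerically finds the (mean, SE) pair whose
moment-matched member reproduces two stated quantiles, for the case where
only an interval is reported. s = 0 yields a flagged point-mass prior, kept
representable so "no uncertainty ⇒ zero value of research" is testable.
Endpoints on [0, 1] use the beta family; other scales use
gamma/lognormal/normal/uniform.

## Elicitation curves and the net-health curve

DALYs averted and additional costs are regressed **independently** on the
endpoint through the elicited points, by ordinary least squares on a
transformed design. Forms: linear (default), quadratic, log-endpoint,
exponential (OLS on log response) and constant. Linear is the default
because elicited tables are small and a straight line through three points
is the most defensible global summary; the other forms exist for clearly
curved relationships. When the number of distinct endpoint values equals the
number of parameters the fit interpolates exactly; fewer distinct values
than parameters is an error, as is a collinear design. A single global form
is fitted rather than a piecewise interpolant: the analysis needs the curve
at *all* plausible endpoint values, including modest extrapolation beyond
the elicited range, which a global form handles transparently. Extrapolation
is never clamped; a warning is emitted when more than 1% of prior mass lies
outside the elicited range. A missing DALY or cost table falls back to a
constant curve at a user-supplied expected value.

The net-health curve is net(x) = d(x) − c(x)/λ_service, by definition,
pointwise.

## Research-value metrics

* **Decision on current evidence**: implement iff E[net(X)] > 0. A tie at
  exactly zero resolves to *not* implementing (conservative; implementing
  gains nothing in expectation but bears the downside risk).
* **Trigger points**: all sign changes of net on the prior's support,
  located by a 2048-cell sign scan plus Brent root-polishing to ~1e−12.
  Reported for interpretation; the value computation does not assume a
  single trigger or a monotone curve.
* **EVR** = E[max(net(X), 0)] − max(E[net(X)], 0). This general form handles
  multi-root and non-monotone net curves and is symmetric between the two
  decision regimes: when the programme is not expected to be cost-effective
  it reduces to E[max(net, 0)], the prior-weighted gains in the favourable
  tail. By Jensen's inequality EVR ≥ 0 always. It is an *upper bound* on the
  value of any actual study, which never resolves all uncertainty.
* **Probability research changes the decision**: prior mass of the region
  where net(X) has the opposite sign to the current decision (the shaded
  tail beyond the trigger in the monotone case).
* **Maximum research spend** = EVR × λ_research. λ_research defaults to
  λ_service — research funds assumed to carry similar opportunity costs —
  and is separately settable because research and service budgets usually
  have different sources.

Expectations use adaptive quadrature (scipy `quad`, absolute/relative
tolerance 1e−10 per segment) over the prior density, with the integration
range split at the trigger points so the kink in max(net, 0) falls on a
segment boundary. Infinite supports are truncated at the 1e−12 extreme
quantiles. An independent Monte-Carlo estimator (`mc_research_value`,
delta-method standard error, seeded) serves as a cross-check; the test suite
requires quadrature–Monte-Carlo agreement within 3 SE at n = 10⁶ across 50
generated scenarios.

## Timing policies

Three policies are valued in expected net DALYs averted, with research
reporting after d years:

* implement now: max(E[net], 0);
* implement alongside research: max(E[net], 0) + f(d)·EVR — implementation
  benefit starts immediately, research benefit only once the study reports;
* delay until research reports: f(d)·(max(E[net], 0) + EVR) — no programme
  access during the research period, everything deferred.

f(d) is the fraction of total discounted benefit weight accruing from year d
onward: annual cohorts enter over a **decision horizon** H with per-year
weights w_t (uniform by default, custom profiles accepted) discounted at
rate r, f(d) = Σ_{t≥d} w_t(1+r)^{−t} / Σ_t w_t(1+r)^{−t}; within-year
benefit accrues uniformly, so fractional d prorates that year. At d = 0 all
three policies coincide; both research-involving policies are nonincreasing
in d; alongside dominates delay whenever implementation has positive
expected value, because alongside never defers the implementation benefit.

Defaults: r = 0.03, H = 10 years, uniform cohorts. The horizon here is *not*
the simulation horizon over which each cohort's DALY consequences are
evaluated (those long-term effects, often 50 years of them, are already
embedded in the elicited DALY figures); it is the window over which the
implementation decision governs incoming cohorts before it would be
revisited anyway. Ten years is a realistic re-evaluation cycle for a
programme-funding decision, and with r = 0.03 it yields the qualitative
orderings expected for an HIV self-testing case study: a 1-year study
defers little (f(1) ≈ 0.886, near-indifference between implementing
alongside and delaying for a costing study), while delaying implementation
for a 3-year outcomes study (f(3) ≈ 0.668) forgoes more health than the
research adds, making delay worse than implementing without research. Exact
reproduction of that study's published policy increments is not attempted:
they derive from a benefit-time model whose functional form is not publicly
specified.

An optional irrecoverable setup cost is converted to DALYs at λ_service and
charged once on implementation to the implement-now and alongside policies;
its expected waste (setup spent, then research overturns the decision,
weighted by the probability of a decision change) is additionally deducted
from the alongside policy's research benefit, and the delay policy incurs it
only with the probability that research ends up supporting implementation.
No salvage benefit is credited after a programme is discontinued.

## Portfolio

Across countries, research value adds: total EVR is the sum of per-country
EVRs, and the total maximum spend converts each country's EVR at that
country's own λ_research — thresholds are never averaged. The league table
ranks proposals by research cost per net DALY averted (ascending; ties break
by label; zero-EVR proposals are retained, flagged as dominated, and listed
last) and reports each proposal's net benefit of research,
EVR − cost/λ_research, flagging negative values as not worthwhile. Proposals
informing overlapping decisions are not additive; the table does not attempt
to correct for that.

## Synthetic scenario generator

`generate_random_scenario(seed)` draws a feasible prior (random family,
mean, SE in realistic ranges: beta means 0.08–0.6 with SE 15–50% of the
feasible maximum, positive-scale families with coefficients of variation
0.1–0.5), a monotone 3–7-point elicitation table with random slope sign,
optional quadratic curvature and a DALY scale of 10²–10⁴, and a cost line
pinned so the net health effect at the prior mean is a uniform random
multiple (±0.6) of the DALY scale. That pinning is what makes the generator
useful: both decision regimes occur frequently, and trigger points land
where the prior has real mass, so research value is usually nonzero. The
elicited range spans the 0.4th–99.6th prior percentiles, keeping
extrapolated mass below the warning threshold.

What the generator does *not* emulate: elicitation noise or expert
disagreement (points lie exactly on the generating curve, so interpolation
properties are exact), correlation between the DALY and cost responses
beyond the pinning construction, multi-modal or heavy-tailed priors, and
non-monotone endpoint–benefit relationships. Passing property tests on these
scenarios therefore demonstrates the correctness of the computations, not
robustness of elicitation practice on messy real-world inputs.

## Numerical and display choices

* Quadrature tolerances 1e−10 (absolute and relative) per segment, limit 200
  subdivisions; tiny negative EVRs within 1e−8 of zero (relative to the net
  scale) are clamped to 0, larger ones raise.
* Trigger scan: 2048 grid cells; roots closer than 1e−9 of the span are
  collapsed.
* Display rounding (reports only; stored values unrounded): DALYs to
  integers, endpoint triggers to 2 decimals, probabilities to 2 decimals,
  currency to the nearest US$100 by default — matching the printed precision
  of published decision tables at the worked-example scale; all steps are
  configurable per scenario.
* All randomness (sampling, Monte-Carlo oracle, scenario generator) flows
  from explicit seeds recorded in configs and outputs.

## Known limitations

* EVR is perfect-information value for a single endpoint: no EVSI, no
  sample-size optimisation, no joint uncertainty over several parameters.
* Regression-coefficient uncertainty is not propagated; only endpoint
  uncertainty enters.
* The timing model is a deterministic deferral-fraction calculation, not an
  optimal-stopping analysis; research duration is fixed, not chosen.
* Opportunity-cost thresholds are inputs; the package takes no view on their
  estimation.
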