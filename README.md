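# voihealth

Practical value-of-research metrics for health programmes.

Research funders, researchers and healthcare decision-makers — particularly in
low- and middle-income countries — routinely face the question of whether a
proposed study (a trial, a costing study, a coverage survey) is worth funding.
`voihealth` answers it with the machinery of value-of-information analysis,
but requires only three assessments that can be assembled at a desk:

1. **a prior on the study endpoint** — current uncertainty about the quantity
   the study would measure, summarised as a mean and standard error for a
   chosen parametric family (beta, normal, gamma, lognormal, uniform);
2. **how the endpoint drives programme value** — a small table of elicited or
   model-derived points giving DALYs averted and additional costs at several
   endpoint values, through which regression curves are fitted;
3. **a health-opportunity-cost threshold** λ (US$/DALY) — the money that,
   spent elsewhere in the health system, would avert one DALY.

## The model

With X the uncertain endpoint, d(x) the fitted DALYs-averted curve and c(x)
the fitted additional-cost curve, the **net DALYs averted** by implementing
the programme when the endpoint equals x are

    net(x) = d(x) − c(x) / λ_service

On current evidence the programme is implemented iff E[net(X)] > 0. The
endpoint values where net(x) crosses zero are **trigger points**: if research
revealed the endpoint beyond a trigger, the implementation decision would
flip. The **expected net DALYs averted via research** — the value of
resolving the endpoint uncertainty, an upper bound on what a real study can
deliver — is

    EVR = E[max(net(X), 0)] − max(E[net(X)], 0)  ≥ 0

and the **maximum justified research spend** is EVR × λ_research, with
λ_research the opportunity cost of research funds (defaulting to λ_service).
Expectations are computed by adaptive quadrature over the prior, with an
independent Monte-Carlo estimator as a cross-check.

On top of this, the package values three timing policies under a discounted
benefit-time profile — implement now, implement alongside research (research
benefit deferred until the study reports), delay implementation until
research reports (everything deferred, no programme access meanwhile) —
aggregates research value across countries at country-specific thresholds,
and ranks competing proposals by research cost per net DALY averted.

## Worked example

An outcomes endpoint on [0, 1] is expected to be 0.10 (SE 0.04); the
programme would avert 1000 / 2000 / 3000 DALYs at endpoint values
0.04 / 0.10 / 0.19, cost a constant US$450,000, and λ = US$300/DALY:

```python
import voihealth as vh

prior = vh.fit_prior(vh.PriorSpec("beta", mean=0.10, se=0.04))
dalys = [(0.04, 1000), (0.10, 2000), (0.19, 3000)]
costs = [(0.04, 450_000), (0.10, 450_000), (0.19, 450_000)]
result = vh.analyse_scenario(prior, dalys, costs, lambda_service=300)
```

or, as a scenario file, `voihealth analyse --config worked.yaml --out report.csv`,
which prints

```
decision on current evidence: implement
expected net DALYs averted:   368
net DALYs averted via research: 59
maximum research spend:       US$17,817
```

Reading: the programme is expected to avert 1868 DALYs (not 2000 — the beta
prior is skewed) at a health opportunity cost of 1500 DALYs, i.e. 368 net
DALYs averted, so it is implemented on current evidence. Below the trigger
point 0.07 the programme would do net harm; the prior puts probability 0.26
there, and weighting the avoided losses by that tail gives 59 net DALYs
averted by research — so a funder should pay at most about US$17,800 for a
study of this endpoint in this setting, which would rank it as a low
research priority.

`vh.plot_scenario(...)` (or `voihealth plot`) draws the two-panel diagnostic:
the net-health curve over the prior density, with the decision-change region
shaded. `vh.compare_policies(...)`, `vh.aggregate_countries(...)` and
`vh.league_table(...)` cover timing, multi-country totals and proposal
ranking; `voihealth generate-fixture --seed N` emits random valid scenarios.

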