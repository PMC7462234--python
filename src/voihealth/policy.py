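"""Valuing the timing of implementation relative to research.

Three policies are compared, all in expected net DALYs averted:

* implement now (no research): ``max(E[net], 0)``;
* implement alongside research: full implementation benefit, but the
  research benefit (EVR) only accrues once the study reports, after
  ``research_duration`` years;
* delay implementation until research reports: everything — both the
  implementation benefit and the research benefit — is deferred, and
  there is no programme access during the research period.

Deferral is priced by a discounted benefit-time profile: annual cohorts
enter over a decision horizon of ``decision_horizon`` years (each cohort's
long-term DALY consequences are already embedded in the net curve), with
benefits discounted at ``discount_rate``.  The fraction of total
discounted benefit weight accruing from year ``d`` onward,

    f(d) = sum_{t>=d} w_t (1+r)^-t / sum_{t>=0} w_t (1+r)^-t,

multiplies whatever a policy defers.  An optional irrecoverable setup
cost (converted to DALYs at ``lambda_service``) is charged on
implementation, and its expected waste — setup spent, then research
overturns the decision — is deducted from the research benefit of the
alongside policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .voi import IMPLEMENT, ResearchValueResult

__all__ = [
    "TimingSpec",
    "PolicyComparison",
    "discount_weight_fraction",
    "compare_policies",
    "report_policy_table",
]


@dataclass(frozen=True)
class TimingSpec:
    """Timing assumptions for the policy comparison.

    Parameters
    ----------
    research_duration : float
        Years until the study reports (d).
    discount_rate : float
        Annual discount rate for health benefits (default 0.03).
    decision_horizon : float
        Years over which the implementation decision generates benefiting
        cohorts before it would be revisited anyway (default 10).
    weights : sequence of float, optional
        Custom nonnegative per-year benefit weights (length = horizon in
        years); default is uniform cohorts.
    irrecoverable_setup_cost : float
        One-off programme setup cost (US$) that cannot be recovered if the
        programme is scaled back.
    research_during_implementation_feasible : bool
        When False the alongside policy is reported as unavailable.
    """

    research_duration: float
    discount_rate: float = 0.03
    decision_horizon: float = 10.0
    weights: tuple[float, ...] | None = None
    irrecoverable_setup_cost: float = 0.0
    research_during_implementation_feasible: bool = True

    def __post_init__(self) -> None:
        if self.research_duration < 0:
            raise ValueError("research_duration must be >= 0")
        if self.research_duration > self.decision_horizon:
            raise ValueError("research_duration cannot exceed decision_horizon")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.decision_horizon <= 0:
            raise ValueError("decision_horizon must be positive")
        if self.irrecoverable_setup_cost < 0:
            raise ValueError("irrecoverable_setup_cost must be >= 0")
        if self.weights is not None:
            w = tuple(float(v) for v in self.weights)
            if any(v < 0 for v in w) or sum(w) <= 0:
                raise ValueError("custom weights must be nonnegative with positive sum")
            object.__setattr__(self, "weights", w)


def _year_weights(spec: TimingSpec) -> np.ndarray:
    n_years = int(math.ceil(spec.decision_horizon))
    if spec.weights is not None:
        w = np.asarray(spec.weights, dtype=float)
    else:
        w = np.ones(n_years)
        w[-1] *= spec.decision_horizon - (n_years - 1)  # prorate a fractional final year
    t = np.arange(w.size, dtype=float)
    return w * (1.0 + spec.discount_rate) ** (-t)


def discount_weight_fraction(spec: TimingSpec, start: float | None = None) -> float:
    """Fraction of total discounted benefit weight accruing from year ``start`` on.

    ``start`` defaults to the research duration.  Benefits within a year
    accrue uniformly, so fractional start times prorate that year's weight.
    Equals 1 at start 0 and 0 at start = horizon.
    """
    d = spec.research_duration if start is None else float(start)
    if d < 0 or d > spec.decision_horizon:
        raise ValueError("start must lie in [0, decision_horizon]")
    dw = _year_weights(spec)
    t = np.arange(dw.size, dtype=float)
    kept = np.clip(t + 1.0 - d, 0.0, 1.0)  # share of year t falling after time d
    return float(np.sum(dw * kept) / np.sum(dw))


@dataclass(frozen=True)
class PolicyComparison:
    """Values of the three timing policies, in expected net DALYs averted.

    ``value_alongside`` is None when implementing alongside research is
    infeasible.  Increments are policy value minus the implement-now value,
    mirroring the "expected net DALYs averted via research" rows of a
    policy report.
    """

    value_implement_now: float
    value_alongside: float | None
    value_delay: float
    research_increment_alongside: float | None
    research_increment_delay: float
    recommended_policy: str
    spec: TimingSpec | None = field(default=None, compare=False)

    @classmethod
    def from_increments(
        cls,
        baseline: float,
        increment_alongside: float | None,
        increment_delay: float,
        spec: TimingSpec | None = None,
    ) -> "PolicyComparison":
        """Build a comparison from a baseline and externally supplied increments."""
        values = {"implement_now": baseline, "delay": baseline + increment_delay}
        alongside = None if increment_alongside is None else baseline + increment_alongside
        if alongside is not None:
            values["alongside"] = alongside
        rec = max(values, key=lambda k: values[k])
        return cls(
            value_implement_now=baseline,
            value_alongside=alongside,
            value_delay=baseline + increment_delay,
            research_increment_alongside=increment_alongside,
            research_increment_delay=increment_delay,
            recommended_policy=rec,
            spec=spec,
        )


def compare_policies(result: ResearchValueResult, spec: TimingSpec) -> PolicyComparison:
    """Value implement-now, implement-alongside-research and delay policies.

    With no setup cost: alongside = implement_now + f(d) * EVR and
    delay = f(d) * (implement_now + EVR); at d = 0 all three coincide.
    A positive irrecoverable setup cost is charged (in DALYs, at
    lambda_service) once on implementation, its expected waste is deducted
    from the alongside research benefit, and the delay policy only incurs
    it with the probability that research supports implementation.
    """
    f = discount_weight_fraction(spec)
    implement_now_base = max(result.expected_net_current, 0.0)
    s = spec.irrecoverable_setup_cost / result.lambda_service
    implements_now = result.decision_current == IMPLEMENT
    p_change = result.prob_decision_change
    p_implement_after = (1.0 - p_change) if implements_now else p_change

    v_now = implement_now_base - s * implements_now
    v_alongside = None
    if spec.research_during_implementation_feasible:
        v_alongside = implement_now_base - s * implements_now + f * (result.evr - s * p_change)
    v_delay = f * (implement_now_base + result.evr - s * p_implement_after)

    values = {"implement_now": v_now, "delay": v_delay}
    if v_alongside is not None:
        values["alongside"] = v_alongside
    rec = max(values, key=lambda k: values[k])
    return PolicyComparison(
        value_implement_now=v_now,
        value_alongside=v_alongside,
        value_delay=v_delay,
        research_increment_alongside=None if v_alongside is None else v_alongside - v_now,
        research_increment_delay=v_delay - v_now,
        recommended_policy=rec,
        spec=spec,
    )


def report_policy_table(comparison: PolicyComparison, lambda_research: float):
    """Tabular policy report (pandas DataFrame).

    One block per research-involving policy with rows: expected net DALYs
    averted via research (the increment over implement-now), potential
    maximum expenditure on the study (increment times ``lambda_research``,
    possibly negative) and the total expected net DALYs averted
    (baseline + increment, exactly).
    """
    import pandas as pd

    if lambda_research <= 0:
        raise ValueError("lambda_research (US$/DALY) must be positive")
    base = comparison.value_implement_now
    rows = [("", "Expected net DALYs averted by implementation", base)]
    blocks = [
        ("Implement testing programme alongside research", comparison.research_increment_alongside),
        ("Delay implementation until research reports", comparison.research_increment_delay),
    ]
    for label, inc in blocks:
        if inc is None:
            rows.append((label, "Policy unavailable", math.nan))
            continue
        rows.append((label, "Expected net DALYs averted via research", inc))
        rows.append((label, "Potential maximum expenditure on study", inc * lambda_research))
        rows.append((label, "Total expected net DALYs averted", base + inc))
    return pd.DataFrame(rows, columns=["policy", "row", "value"])
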