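"""Multi-country aggregation and research league tables.

A study often informs decisions in several countries; its total value is
the sum of per-country net DALYs averted by research, each converted to a
maximum spend at that country's own opportunity-cost threshold (thresholds
are never averaged).  Competing proposals are ranked by research cost per
net DALY averted — a cost-effectiveness league table for research — and by
the net benefit of research, EVR minus the health opportunity cost of the
research budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .voi import ResearchValueResult

__all__ = ["CountryScenario", "ResearchProposal", "aggregate_countries", "league_table"]


@dataclass(frozen=True)
class CountryScenario:
    """One country's research-value result with its own thresholds (US$/DALY)."""

    label: str
    result: ResearchValueResult
    lambda_service: float
    lambda_research: float


@dataclass(frozen=True)
class ResearchProposal:
    """A proposal with its aggregated research value and its price tag."""

    label: str
    evr: float
    research_cost: float

    def __post_init__(self) -> None:
        if self.research_cost < 0:
            raise ValueError(f"proposal {self.label!r}: research_cost must be >= 0")
        if self.evr < 0:
            raise ValueError(f"proposal {self.label!r}: evr must be >= 0")


def aggregate_countries(scenarios: list[CountryScenario]) -> tuple[float, float]:
    """Total EVR and total maximum research spend across countries.

    Each country's EVR is converted at that country's research threshold
    before summing.  Duplicate labels are rejected.
    """
    if not scenarios:
        raise ValueError("aggregate_countries requires a nonempty scenario list")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate country labels: {dupes}")
    total_evr = sum(s.result.evr for s in scenarios)
    total_spend = sum(s.result.evr * s.lambda_research for s in scenarios)
    return float(total_evr), float(total_spend)


def league_table(proposals: list[ResearchProposal], lambda_research: float) -> pd.DataFrame:
    """Rank proposals by research cost per net DALY averted (ascending).

    Proposals with zero EVR are dominated (any spend buys no health) and
    are listed last, flagged, rather than dropped.  Ties in cost per DALY
    break by label.  ``net_benefit_dalys = evr - research_cost /
    lambda_research``; negative values flag proposals not worth funding at
    the stated opportunity cost of research funds.
    """
    if lambda_research <= 0:
        raise ValueError("lambda_research (US$/DALY) must be positive")
    rows = []
    for p in proposals:
        ratio = p.research_cost / p.evr if p.evr > 0 else np.inf
        rows.append(
            {
                "label": p.label,
                "evr_dalys": p.evr,
                "research_cost": p.research_cost,
                "cost_per_daly_averted": ratio,
                "net_benefit_dalys": p.evr - p.research_cost / lambda_research,
                "dominated": p.evr <= 0,
                "worthwhile": p.evr > 0 and ratio <= lambda_research,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        ["dominated", "cost_per_daly_averted", "label"], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
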