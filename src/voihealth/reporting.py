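"""Report tables and the two-panel diagnostic figure.

Reports mirror the row labels of published decision tables: the
implications of deciding without further research (expected DALYs averted,
costs, opportunity cost, ICER, net DALYs averted) and with further
research (trigger value, probability of a decision change, expected net
DALYs averted via research, maximum study expenditure, total).  Each row
carries both a display-rounded value and the unrounded number it came
from.

The figure stacks the net-health curve over the prior density on a shared
endpoint axis and shades the region where research would change the
decision — the region whose prior-weighted net losses (or gains) are what
research is worth.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RoundingRules
from .policy import PolicyComparison
from .voi import IMPLEMENT, ResearchValueResult

__all__ = ["report_rows", "write_report", "plot_scenario"]

# Row labels, verbatim from standard published layouts.
ROW_EXPECTED_DALYS = "Expected DALYs averted by programme"
ROW_EXPECTED_COST = "Expected additional long-term costs associated with programme"
ROW_OPPORTUNITY = "Expected health opportunity costs of funding programme (DALYs incurred)"
ROW_ICER = "Incremental cost-effectiveness ratio (US$/DALY)"
ROW_NET = "Expected net DALYs averted by implementation"
ROW_TRIGGER = "Value of endpoint at which decision changes"
ROW_PROB = "Probability further research could change decision"
ROW_EVR = "Expected net DALYs averted via research"
ROW_MAX_SPEND = "Potential maximum expenditure on study"
ROW_TOTAL = "Total expected net DALYs averted"


def report_rows(
    result: ResearchValueResult,
    comparison: PolicyComparison | None = None,
    rounding: RoundingRules | None = None,
) -> pd.DataFrame:
    """Assemble the report as a DataFrame (section, row, value, unrounded)."""
    r = rounding or RoundingRules()
    rows: list[tuple[str, str, float, float]] = []

    sec = "Implications of decision making without further research"
    if result.expected_dalys is not None:
        rows.append((sec, ROW_EXPECTED_DALYS, r.dalys(result.expected_dalys), result.expected_dalys))
    if result.expected_cost is not None:
        rows.append((sec, ROW_EXPECTED_COST, r.currency(result.expected_cost), result.expected_cost))
    if result.opportunity_cost_dalys is not None:
        rows.append((sec, ROW_OPPORTUNITY, r.dalys(result.opportunity_cost_dalys),
                     result.opportunity_cost_dalys))
    if result.icer is not None and math.isfinite(result.icer):
        rows.append((sec, ROW_ICER, round(result.icer), result.icer))
    rows.append((sec, ROW_NET, r.dalys(result.expected_net_current), result.expected_net_current))

    sec = "Implications of decision making informed by further research"
    for t in result.trigger_points:
        rows.append((sec, ROW_TRIGGER, r.endpoint(t), t))
    rows.append((sec, ROW_PROB, r.probability(result.prob_decision_change),
                 result.prob_decision_change))
    rows.append((sec, ROW_EVR, r.dalys(result.evr), result.evr))
    rows.append((sec, ROW_MAX_SPEND, r.currency(result.max_research_spend),
                 result.max_research_spend))
    rows.append((sec, ROW_TOTAL, r.dalys(result.total_with_research), result.total_with_research))

    if comparison is not None:
        base = comparison.value_implement_now
        blocks = [
            ("Implement testing programme alongside research",
             comparison.research_increment_alongside),
            ("Delay implementation until research reports", comparison.research_increment_delay),
        ]
        for sec, inc in blocks:
            if inc is None:
                continue
            rows.append((sec, ROW_EVR, r.dalys(inc), inc))
            spend = inc * result.lambda_research
            rows.append((sec, ROW_MAX_SPEND, r.currency(spend), spend))
            rows.append((sec, ROW_TOTAL, r.dalys(base + inc), base + inc))

    return pd.DataFrame(rows, columns=["section", "row", "value", "unrounded"])


def write_report(
    result: ResearchValueResult,
    path: str | Path,
    comparison: PolicyComparison | None = None,
    rounding: RoundingRules | None = None,
) -> pd.DataFrame:
    """Write the report CSV and return the DataFrame."""
    df = report_rows(result, comparison, rounding)
    df.to_csv(path, index=False)
    return df


def plot_scenario(
    prior,
    net,
    result: ResearchValueResult,
    path: str | Path,
    n_grid: int = 512,
) -> None:
    """Two aligned panels: net DALYs averted vs endpoint, and the prior.

    The endpoint region where research would flip the implementation
    decision is shaded in both panels; trigger points are marked on the
    zero line.  Written as PNG or SVG according to the file suffix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = prior.integration_bounds(tail=1e-4)
    if hi <= lo:  # point-mass prior: show a small window around the atom
        pad = max(abs(prior.mean), 1.0) * 0.1
        lo, hi = prior.mean - pad, prior.mean + pad
    xs = np.linspace(lo, hi, n_grid)
    ys = np.asarray(net(xs), dtype=float)

    fig, (ax_net, ax_prior) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 6), height_ratios=[3, 2]
    )
    ax_net.plot(xs, ys, color="tab:blue", lw=2)
    ax_net.axhline(0.0, color="black", lw=0.8)
    ax_net.set_ylabel("Net DALYs averted by programme")

    implement = result.decision_current == IMPLEMENT
    edges = [lo, *[t for t in result.trigger_points if lo < t < hi], hi]
    shaded = []
    for a, b in zip(edges, edges[1:]):
        mid_net = float(net(0.5 * (a + b)))
        if (mid_net < 0) if implement else (mid_net > 0):
            shaded.append((a, b))
    for a, b in shaded:
        ax_net.axvspan(a, b, color="tab:red", alpha=0.2)
        ax_prior.axvspan(a, b, color="tab:red", alpha=0.2)
    for t in result.trigger_points:
        if lo <= t <= hi:
            ax_net.axvline(t, color="tab:red", ls="--", lw=1)
            ax_net.annotate(f"trigger {t:.2f}", (t, 0), textcoords="offset points",
                            xytext=(4, 6), fontsize=8, color="tab:red")
    if not shaded:
        ax_net.annotate(
            "research cannot change decision", xy=(0.5, 0.9),
            xycoords="axes fraction", ha="center", fontsize=9, color="dimgray",
        )

    if prior.degenerate:
        ax_prior.axvline(prior.mean, color="tab:blue", lw=2)
    else:
        ax_prior.plot(xs, prior.pdf(xs), color="tab:blue", lw=2)
        ax_prior.fill_between(xs, prior.pdf(xs), alpha=0.15, color="tab:blue")
    ax_prior.set_ylabel("Prior density")
    ax_prior.set_xlabel("Value of endpoint")

    decision = "implement" if implement else "do not implement"
    ax_net.set_title(
        f"E[net] = {result.expected_net_current:,.0f} DALYs ({decision}); "
        f"research worth {result.evr:,.0f} DALYs"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
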