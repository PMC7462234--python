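"""Scenario configuration: schema, YAML/JSON round-trip, random generator.

A scenario bundles everything one analysis needs: the endpoint prior, the
elicitation table (inline or a 3-column CSV), the opportunity-cost
thresholds, optional timing assumptions, display-rounding rules and a
random seed.  ``run_scenario`` orchestrates the full pipeline from a
config to a :class:`~voihealth.voi.ResearchValueResult`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .elicitation import CURVE_FORMS, ElicitationPoint, NetHealthCurve, build_net_curve, fit_curve
from .policy import PolicyComparison, TimingSpec, compare_policies
from .priors import FAMILIES, FittedPrior, PriorSpec, fit_prior
from .voi import ResearchValueResult, analyse_scenario

__all__ = [
    "RoundingRules",
    "ScenarioConfig",
    "ScenarioConfigError",
    "ScenarioOutputs",
    "read_scenario",
    "write_scenario",
    "run_scenario",
    "generate_random_scenario",
]

log = logging.getLogger("voihealth")


class ScenarioConfigError(ValueError):
    """Scenario file violates the schema; message lists the offending keys."""


@dataclass(frozen=True)
class RoundingRules:
    """Display rounding: DALYs to integers, endpoints to 2 dp, currency to $100.

    Matches the precision conventions of published decision tables; stored
    values are always unrounded.
    """

    dalys_decimals: int = 0
    endpoint_decimals: int = 2
    probability_decimals: int = 2
    currency_step: float = 100.0

    def dalys(self, v: float) -> float:
        return round(v, self.dalys_decimals)

    def endpoint(self, v: float) -> float:
        return round(v, self.endpoint_decimals)

    def probability(self, v: float) -> float:
        return round(v, self.probability_decimals)

    def currency(self, v: float) -> float:
        if self.currency_step <= 0:
            return v
        return round(v / self.currency_step) * self.currency_step


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated scenario: prior + elicitation + thresholds (+ timing)."""

    prior: PriorSpec
    points: tuple[ElicitationPoint, ...]
    lambda_service: float
    lambda_research: float
    dalys_form: str = "linear"
    cost_form: str = "linear"
    timing: TimingSpec | None = None
    rounding: RoundingRules = field(default_factory=RoundingRules)
    seed: int | None = None
    label: str | None = None


@dataclass(frozen=True)
class ScenarioOutputs:
    """Everything computed from one scenario."""

    config: ScenarioConfig
    prior: FittedPrior
    net: NetHealthCurve
    result: ResearchValueResult
    comparison: PolicyComparison | None = None


# ---------------------------------------------------------------------------
# reading / writing


def _require(block: dict, keys: Sequence[str], where: str, errors: list[str]) -> None:
    for k in keys:
        if k not in block:
            errors.append(f"{where}.{k} missing")


def _parse_points(elic: dict, base_dir: Path, errors: list[str]) -> tuple[ElicitationPoint, ...]:
    if "csv" in elic:
        path = base_dir / str(elic["csv"])
        if not path.exists():
            errors.append(f"elicitation.csv file not found: {path}")
            return ()
        df = pd.read_csv(path)
        needed = {"endpoint", "dalys_averted", "additional_cost"}
        if not needed.issubset(df.columns):
            errors.append(f"elicitation.csv must have columns {sorted(needed)}")
            return ()
        rows = df[["endpoint", "dalys_averted", "additional_cost"]].to_numpy(dtype=float)
        return tuple(ElicitationPoint(*r) for r in rows)
    raw = elic.get("points")
    if not isinstance(raw, list) or len(raw) < 2:
        errors.append("elicitation.points must be a list of >= 2 entries")
        return ()
    pts = []
    for i, row in enumerate(raw):
        try:
            if isinstance(row, dict):
                pts.append(
                    ElicitationPoint(
                        float(row["endpoint"]),
                        float(row["dalys_averted"]),
                        float(row["additional_cost"]),
                    )
                )
            else:
                x, d, c = row
                pts.append(ElicitationPoint(float(x), float(d), float(c)))
        except (KeyError, TypeError, ValueError):
            errors.append(f"elicitation.points[{i}] malformed (need endpoint, dalys_averted, additional_cost)")
    return tuple(pts)


def config_from_dict(data: dict[str, Any], base_dir: Path | str = ".") -> ScenarioConfig:
    """Validate a raw mapping into a :class:`ScenarioConfig`.

    Raises :class:`ScenarioConfigError` listing every offending key rather
    than stopping at the first.
    """
    if not isinstance(data, dict):
        raise ScenarioConfigError("scenario config must be a mapping")
    errors: list[str] = []
    base_dir = Path(base_dir)

    prior_block = data.get("prior")
    prior_spec = None
    if not isinstance(prior_block, dict):
        errors.append("prior block missing or not a mapping")
    else:
        missing_before = len(errors)
        _require(prior_block, ("family", "mean", "se"), "prior", errors)
        if len(errors) == missing_before:
            try:
                quant = prior_block.get("quantiles")
                prior_spec = PriorSpec(
                    family=str(prior_block["family"]),
                    mean=float(prior_block["mean"]),
                    se=float(prior_block["se"]),
                    quantiles=tuple((float(p), float(v)) for p, v in quant) if quant else None,
                )
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"prior: {exc}")

    elic = data.get("elicitation")
    points: tuple[ElicitationPoint, ...] = ()
    dalys_form = cost_form = "linear"
    if not isinstance(elic, dict):
        errors.append("elicitation block missing or not a mapping")
    else:
        points = _parse_points(elic, base_dir, errors)
        dalys_form = str(elic.get("dalys_form", "linear"))
        cost_form = str(elic.get("cost_form", "linear"))
        for name, form in (("dalys_form", dalys_form), ("cost_form", cost_form)):
            if form not in CURVE_FORMS:
                errors.append(f"elicitation.{name} must be one of {CURVE_FORMS}")

    thresholds = data.get("thresholds")
    lam_s = lam_r = None
    if not isinstance(thresholds, dict) or "lambda_service" not in thresholds:
        errors.append("thresholds.lambda_service missing")
    else:
        try:
            lam_s = float(thresholds["lambda_service"])
            if lam_s <= 0:
                errors.append("thresholds.lambda_service must be positive")
        except (TypeError, ValueError):
            errors.append("thresholds.lambda_service must be a number")
        if "lambda_research" in thresholds:
            try:
                lam_r = float(thresholds["lambda_research"])
                if lam_r <= 0:
                    errors.append("thresholds.lambda_research must be positive")
            except (TypeError, ValueError):
                errors.append("thresholds.lambda_research must be a number")
        elif lam_s is not None:
            lam_r = lam_s
            log.warning("lambda_research not set; defaulting to lambda_service = %s", lam_s)

    timing = None
    if "timing" in data and data["timing"] is not None:
        tb = data["timing"]
        if not isinstance(tb, dict) or "research_duration" not in tb:
            errors.append("timing.research_duration missing")
        else:
            try:
                timing = TimingSpec(
                    research_duration=float(tb["research_duration"]),
                    discount_rate=float(tb.get("discount_rate", 0.03)),
                    decision_horizon=float(tb.get("decision_horizon", 10.0)),
                    weights=tuple(tb["weights"]) if tb.get("weights") else None,
                    irrecoverable_setup_cost=float(tb.get("irrecoverable_setup_cost", 0.0)),
                    research_during_implementation_feasible=bool(
                        tb.get("research_during_implementation_feasible", True)
                    ),
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"timing: {exc}")

    rounding = RoundingRules()
    if "rounding" in data and data["rounding"] is not None:
        rb = data["rounding"]
        if not isinstance(rb, dict):
            errors.append("rounding block must be a mapping")
        else:
            try:
                rounding = RoundingRules(
                    dalys_decimals=int(rb.get("dalys_decimals", 0)),
                    endpoint_decimals=int(rb.get("endpoint_decimals", 2)),
                    probability_decimals=int(rb.get("probability_decimals", 2)),
                    currency_step=float(rb.get("currency_step", 100.0)),
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"rounding: {exc}")

    if errors:
        raise ScenarioConfigError("invalid scenario config: " + "; ".join(errors))
    return ScenarioConfig(
        prior=prior_spec,
        points=points,
        lambda_service=lam_s,
        lambda_research=lam_r,
        dalys_form=dalys_form,
        cost_form=cost_form,
        timing=timing,
        rounding=rounding,
        seed=int(data["seed"]) if data.get("seed") is not None else None,
        label=str(data["label"]) if data.get("label") is not None else None,
    )


def read_scenario(path: str | Path) -> ScenarioConfig:
    """Read and validate a YAML or JSON scenario file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioConfigError(f"could not parse {path}: {exc}") from exc
    return config_from_dict(data, base_dir=path.parent)


def config_to_dict(cfg: ScenarioConfig) -> dict[str, Any]:
    """Serialisable mapping; inverse of :func:`config_from_dict` on semantic fields."""
    out: dict[str, Any] = {
        "prior": {
            "family": cfg.prior.family,
            "mean": float(cfg.prior.mean),
            "se": float(cfg.prior.se),
        },
        "elicitation": {
            "points": [
                {"endpoint": p.endpoint_value, "dalys_averted": p.dalys_averted,
                 "additional_cost": p.additional_cost}
                for p in cfg.points
            ],
            "dalys_form": cfg.dalys_form,
            "cost_form": cfg.cost_form,
        },
        "thresholds": {
            "lambda_service": cfg.lambda_service,
            "lambda_research": cfg.lambda_research,
        },
        "rounding": {
            "dalys_decimals": cfg.rounding.dalys_decimals,
            "endpoint_decimals": cfg.rounding.endpoint_decimals,
            "probability_decimals": cfg.rounding.probability_decimals,
            "currency_step": cfg.rounding.currency_step,
        },
    }
    if cfg.prior.quantiles:
        out["prior"]["quantiles"] = [[p, v] for p, v in cfg.prior.quantiles]
    if cfg.timing is not None:
        t = cfg.timing
        out["timing"] = {
            "research_duration": t.research_duration,
            "discount_rate": t.discount_rate,
            "decision_horizon": t.decision_horizon,
            "irrecoverable_setup_cost": t.irrecoverable_setup_cost,
            "research_during_implementation_feasible": t.research_during_implementation_feasible,
        }
        if t.weights is not None:
            out["timing"]["weights"] = list(t.weights)
    if cfg.seed is not None:
        out["seed"] = cfg.seed
    if cfg.label is not None:
        out["label"] = cfg.label
    return out


def write_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario config as YAML; ``read_scenario`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


# ---------------------------------------------------------------------------
# orchestration


def run_scenario(cfg: ScenarioConfig) -> ScenarioOutputs:
    """Run the full analysis pipeline for one scenario config."""
    prior = fit_prior(cfg.prior)
    xy_dalys = [(p.endpoint_value, p.dalys_averted) for p in cfg.points]
    xy_cost = [(p.endpoint_value, p.additional_cost) for p in cfg.points]
    result = analyse_scenario(
        prior,
        xy_dalys,
        xy_cost,
        cfg.lambda_service,
        cfg.lambda_research,
        dalys_form=cfg.dalys_form,
        cost_form=cfg.cost_form,
    )
    net = build_net_curve(
        fit_curve(xy_dalys, cfg.dalys_form), fit_curve(xy_cost, cfg.cost_form), cfg.lambda_service
    )
    comparison = compare_policies(result, cfg.timing) if cfg.timing is not None else None
    return ScenarioOutputs(config=cfg, prior=prior, net=net, result=result, comparison=comparison)


# ---------------------------------------------------------------------------
# random scenario generator (property-test fixtures)


def generate_random_scenario(
    seed: int,
    curvature_prob: float = 0.3,
    n_points: int | None = None,
) -> ScenarioConfig:
    """Draw a random, always-valid scenario; reproducible by seed.

    Samples a feasible prior (random family, mean, SE), a monotone 3-7
    point elicitation table with random slope sign and optional curvature,
    and a cost line pinned so the net health effect at the prior mean is a
    random multiple of the DALY scale — which makes both decision regimes
    (cost-effective and not) occur with substantial probability, and puts
    the trigger point where the prior has real mass.
    """
    rng = np.random.default_rng(seed)
    family = rng.choice(FAMILIES, p=[0.4, 0.15, 0.15, 0.15, 0.15])
    if family in ("beta", "uniform"):
        mean = float(rng.uniform(0.08, 0.6))
        se = float(rng.uniform(0.15, 0.5)) * math.sqrt(mean * (1 - mean))
    elif family == "normal":
        mean = float(rng.uniform(0.5, 5.0))
        se = mean * float(rng.uniform(0.1, 0.4))
    else:  # gamma, lognormal
        mean = float(rng.uniform(0.5, 5.0))
        se = mean * float(rng.uniform(0.1, 0.5))
    prior_spec = PriorSpec(family=str(family), mean=mean, se=se)
    prior = fit_prior(prior_spec)

    n = int(n_points) if n_points is not None else int(rng.integers(3, 8))
    # keep <1% prior mass outside the elicited range
    probs = np.linspace(0.004, 0.996, n)
    xs = np.asarray(prior.quantile(probs), dtype=float)

    scale = 10.0 ** rng.uniform(2.0, 4.0)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    curved = rng.random() < curvature_prob
    c = float(rng.uniform(0.2, 1.0)) if curved else 0.0
    u = (xs - xs[0]) / (xs[-1] - xs[0])
    dalys = sign * scale * (u + c * u * u)
    dalys_form = "quadratic" if curved else "linear"

    lam_s = float(np.round(rng.uniform(100, 1000)))
    # pin net(mean) to a random offset of the DALY scale (either sign)
    target_net_at_mean = float(rng.uniform(-0.6, 0.6)) * scale
    u_mean = (prior.mean - xs[0]) / (xs[-1] - xs[0])
    dalys_at_mean = sign * scale * (u_mean + c * u_mean * u_mean)
    cost_slope = lam_s * sign * scale / (xs[-1] - xs[0]) * float(rng.uniform(-0.3, 0.3))
    cost_intercept = lam_s * (dalys_at_mean - target_net_at_mean) - cost_slope * prior.mean
    costs = cost_intercept + cost_slope * xs

    points = tuple(
        ElicitationPoint(float(x), float(d), float(co)) for x, d, co in zip(xs, dalys, costs)
    )
    return ScenarioConfig(
        prior=prior_spec,
        points=points,
        lambda_service=lam_s,
        lambda_research=lam_s,
        dalys_form=dalys_form,
        cost_form="linear",
        seed=int(seed),
        label=f"synthetic-{seed}",
    )
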