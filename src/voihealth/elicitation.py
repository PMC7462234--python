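"""Regression curves linking a study endpoint to programme DALYs and costs.

A small table of elicited (or model-derived) points — "if the endpoint
were x, the programme would avert y DALYs and cost c dollars" — is turned
into two independently fitted regression curves: DALYs averted on the
endpoint and additional cost on the endpoint.  Combining them with a
health-opportunity-cost threshold lambda (US$ per DALY) gives the net
health curve

    net(x) = dalys(x) - cost(x) / lambda

i.e. DALYs gained directly minus DALYs forgone elsewhere in the health
system because the programme's cost displaces other spending.

The default functional form is ordinary least squares on the raw endpoint
(linear); quadratic, log-endpoint, exponential (log-response) and constant
forms are available for nonlinear relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "CURVE_FORMS",
    "ElicitationPoint",
    "FittedCurve",
    "NetHealthCurve",
    "SingularDesignError",
    "fit_curve",
    "constant_curve",
    "build_net_curve",
    "prior_mass_outside_range",
]

CURVE_FORMS = ("linear", "quadratic", "log_endpoint", "exponential", "constant")

_N_PARAMS = {"linear": 2, "quadratic": 3, "log_endpoint": 2, "exponential": 2, "constant": 1}


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient (collinear predictors)."""


class ElicitationPoint(NamedTuple):
    """One elicited scenario: endpoint value with its DALY and cost consequences."""

    endpoint_value: float
    dalys_averted: float
    additional_cost: float


def _design(form: str, x: np.ndarray) -> np.ndarray:
    if form == "linear":
        return np.column_stack([np.ones_like(x), x])
    if form == "quadratic":
        return np.column_stack([np.ones_like(x), x, x * x])
    if form in ("log_endpoint",):
        if np.any(x <= 0):
            raise ValueError("log_endpoint form requires strictly positive endpoint values")
        return np.column_stack([np.ones_like(x), np.log(x)])
    if form == "exponential":
        return np.column_stack([np.ones_like(x), x])
    if form == "constant":
        return np.ones((x.size, 1))
    raise ValueError(f"unknown curve form {form!r}; expected one of {CURVE_FORMS}")


@dataclass(frozen=True)
class FittedCurve:
    """An OLS-fitted response curve on the endpoint.

    ``coef`` holds the coefficients of the (possibly transformed) design:
    linear ``y = c0 + c1 x``; quadratic ``y = c0 + c1 x + c2 x^2``;
    log_endpoint ``y = c0 + c1 ln x``; exponential ``y = exp(c0 + c1 x)``;
    constant ``y = c0``.
    """

    form: str
    coef: tuple[float, ...]
    rss: float
    n_points: int
    x_range: tuple[float, float]

    def predict(self, x):
        """Evaluate the fitted form at ``x`` (scalar or array)."""
        x_arr = np.asarray(x, dtype=float)
        scalar = x_arr.ndim == 0
        x_arr = np.atleast_1d(x_arr)
        if self.form in ("log_endpoint",) and np.any(x_arr <= 0):
            raise ValueError(f"{self.form} curve cannot be evaluated at endpoint <= 0")
        design = _design(self.form, x_arr)
        y = design @ np.asarray(self.coef)
        if self.form == "exponential":
            y = np.exp(y)
        return float(y[0]) if scalar else y

    __call__ = predict


def fit_curve(
    points: Iterable[tuple[float, float]],
    form: str = "linear",
) -> FittedCurve:
    """Fit a response curve through elicited (endpoint, response) points.

    Ordinary least squares on the transformed design; closed form and
    deterministic.  When the number of distinct endpoint values equals the
    number of parameters the fit interpolates the points exactly.

    Raises
    ------
    ValueError
        Fewer distinct endpoint values than curve parameters, or a form
        infeasible for the data (log at x <= 0, exponential at y <= 0).
    SingularDesignError
        Collinear design (e.g. duplicate transformed predictor values).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if form not in CURVE_FORMS:
        raise ValueError(f"unknown curve form {form!r}; expected one of {CURVE_FORMS}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    n_distinct = np.unique(x).size
    need = _N_PARAMS[form]
    if n_distinct < max(need, 2) and not (form == "constant" and n_distinct >= 1):
        raise ValueError(
            f"{form} form needs at least {max(need, 2)} distinct endpoint values, got {n_distinct}"
        )
    design = _design(form, x)
    resp = y
    if form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential form requires strictly positive responses")
        resp = np.log(y)
    coef, _, rank, _ = np.linalg.lstsq(design, resp, rcond=None)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"singular design for {form} form: transformed predictors are collinear"
        )
    fitted = design @ coef
    if form == "exponential":
        fitted = np.exp(fitted)
    rss = float(np.sum((y - fitted) ** 2))
    return FittedCurve(
        form=form,
        coef=tuple(float(c) for c in coef),
        rss=rss,
        n_points=len(pts),
        x_range=(float(x.min()), float(x.max())),
    )


def constant_curve(value: float) -> FittedCurve:
    """A curve that is constant in the endpoint (e.g. cost not varying with it)."""
    v = float(value)
    return FittedCurve(form="constant", coef=(v,), rss=0.0, n_points=0,
                       x_range=(-np.inf, np.inf))


@dataclass(frozen=True)
class NetHealthCurve:
    """Net DALYs averted as a function of the endpoint.

    net(x) = dalys_curve(x) - cost_curve(x) / lambda_service, where
    lambda_service (US$/DALY) converts programme cost into health forgone
    elsewhere in the system.
    """

    dalys_curve: FittedCurve
    cost_curve: FittedCurve
    lambda_service: float

    def __call__(self, x):
        return self.dalys_curve.predict(x) - self.cost_curve.predict(x) / self.lambda_service

    @property
    def is_linear(self) -> bool:
        return all(c.form in ("linear", "constant") for c in (self.dalys_curve, self.cost_curve))


def build_net_curve(
    dalys_curve: FittedCurve,
    cost_curve: FittedCurve,
    lambda_service: float,
) -> NetHealthCurve:
    """Combine DALY and cost curves into a net health curve at threshold lambda."""
    if lambda_service <= 0:
        raise ValueError("lambda_service (US$/DALY) must be positive")
    return NetHealthCurve(dalys_curve, cost_curve, float(lambda_service))


def prior_mass_outside_range(prior, x_range: Sequence[float]) -> float:
    """Prior mass lying outside the elicited endpoint range."""
    lo, hi = x_range
    return float(prior.cdf(lo) + (1.0 - prior.cdf(hi)))


def warn_if_extrapolating(prior, curve: FittedCurve, threshold: float = 0.01) -> None:
    """Warn when more than ``threshold`` prior mass sits outside the elicited range.

    The fitted form is still evaluated there (no clamping); the warning
    flags that the net-health curve rests on extrapolation.
    """
    if curve.n_points == 0:
        return
    mass = prior_mass_outside_range(prior, curve.x_range)
    if mass > threshold:
        warnings.warn(
            f"{mass:.1%} of prior mass lies outside the elicited endpoint range "
            f"{curve.x_range}; the fitted {curve.form} curve is extrapolated there",
            stacklevel=2,
        )
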