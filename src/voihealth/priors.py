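"""Parametric priors for an uncertain study endpoint.

Current knowledge about a study endpoint (a response probability, a unit
cost, a coverage proportion...) is summarised as a parametric probability
distribution — a prior — specified by its mean and standard error.
Parameters are obtained by moment matching, so the specified mean/SE are
reproduced exactly; any reported credible interval is then a *consequence*
of the fitted prior and is exposed as a diagnostic, never enforced as a
constraint.

Supported families: beta (endpoints on [0, 1]), normal, gamma, lognormal
(positive endpoints) and uniform.  A zero-SE specification yields a
point-mass prior, which is the natural vehicle for "no uncertainty implies
zero value of research" checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "PriorSpec",
    "FittedPrior",
    "InfeasibleMomentsError",
    "fit_prior",
    "fit_prior_from_quantiles",
]

FAMILIES = ("beta", "normal", "gamma", "lognormal", "uniform")

#: SE below this (relative to max(|mean|, 1)) is treated as a point mass.
_DEGENERATE_TOL = 1e-12


class InfeasibleMomentsError(ValueError):
    """The requested mean/SE cannot be realised by the requested family."""


@dataclass(frozen=True)
class PriorSpec:
    """Summary specification of a prior: family plus mean and standard error.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    mean, se : float
        Target mean and standard error on the endpoint scale; ``se == 0``
        requests a point mass.
    quantiles : sequence of (probability, value), optional
        Reported quantiles (e.g. a published 95% CI).  Treated as
        diagnostics: the fit reports the achieved quantiles next to them
        but does not constrain the parameters.
    """

    family: str
    mean: float
    se: float
    quantiles: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}; expected one of {FAMILIES}")
        if not math.isfinite(self.mean):
            raise ValueError("prior mean must be finite")
        if self.se < 0 or not math.isfinite(self.se):
            raise ValueError("prior se must be finite and >= 0")
        if self.quantiles is not None:
            qs = tuple((float(p), float(v)) for p, v in self.quantiles)
            probs = [p for p, _ in qs]
            if any(not 0 < p < 1 for p in probs):
                raise ValueError("quantile probabilities must lie in (0, 1)")
            if any(b <= a for a, b in zip(probs, probs[1:])):
                raise ValueError("quantile probabilities must be strictly increasing")
            object.__setattr__(self, "quantiles", qs)


@dataclass(frozen=True)
class FittedPrior:
    """A fitted prior: a frozen scipy distribution plus its provenance.

    ``dist`` is ``None`` only for the degenerate (point-mass) prior, in
    which case all distribution functions are the obvious step/constant
    limits.
    """

    family: str
    params: dict[str, float]
    mean: float
    se: float
    support: tuple[float, float]
    degenerate: bool = False
    quantile_diagnostics: tuple[tuple[float, float, float], ...] = ()
    dist: object | None = field(default=None, repr=False, compare=False)

    # -- distribution functions -------------------------------------------
    def pdf(self, x):
        """Density at ``x``; zero outside the support (inf at a point mass atom)."""
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            out = np.where(x == self.mean, np.inf, 0.0)
            return out if out.ndim else float(out)
        lo, hi = self.support
        out = np.where((x < lo) | (x > hi), 0.0, self.dist.pdf(np.clip(x, lo, hi)))
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            out = np.where(x >= self.mean, 1.0, 0.0)
            return out if out.ndim else float(out)
        out = np.clip(self.dist.cdf(x), 0.0, 1.0)
        return out if out.ndim else float(out)

    def quantile(self, p):
        """Inverse CDF; ``p`` must lie in (0, 1)."""
        p_arr = np.asarray(p, dtype=float)
        if np.any((p_arr <= 0) | (p_arr >= 1)):
            raise ValueError("quantile probability must lie strictly in (0, 1)")
        if self.degenerate:
            out = np.full_like(p_arr, self.mean)
            return out if out.ndim else float(out)
        out = self.dist.ppf(p_arr)
        return out if out.ndim else float(out)

    def sample(self, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
        """Draw ``n`` endpoint values; reproducible for a fixed ``seed``."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if self.degenerate:
            return np.full(n, self.mean)
        return np.asarray(self.dist.rvs(size=n, random_state=rng))

    def integration_bounds(self, tail: float = 1e-12) -> tuple[float, float]:
        """Finite bounds carrying all but ``2*tail`` of the prior mass.

        Finite supports are returned as-is; infinite tails are cut at
        extreme quantiles so quadrature and root scans operate on a
        finite interval.
        """
        if self.degenerate:
            return (self.mean, self.mean)
        lo, hi = self.support
        if not math.isfinite(lo):
            lo = float(self.dist.ppf(tail))
        if not math.isfinite(hi):
            hi = float(self.dist.ppf(1.0 - tail))
        return (lo, hi)


def _moment_params(family: str, m: float, s: float) -> tuple[dict[str, float], object, tuple[float, float]]:
    """Moment-matched natural parameters, frozen dist and support per family."""
    v = s * s
    if family == "beta":
        if not 0.0 < m < 1.0:
            raise InfeasibleMomentsError(f"beta prior requires 0 < mean < 1, got mean={m}")
        if v >= m * (1.0 - m):
            raise InfeasibleMomentsError(
                f"beta prior requires se**2 < mean*(1-mean): se**2={v:g} >= {m * (1 - m):g}"
            )
        nu = m * (1.0 - m) / v - 1.0
        a, b = m * nu, (1.0 - m) * nu
        return {"shape1": a, "shape2": b}, stats.beta(a, b), (0.0, 1.0)
    if family == "normal":
        return {"loc": m, "scale": s}, stats.norm(m, s), (-math.inf, math.inf)
    if family == "gamma":
        if m <= 0:
            raise InfeasibleMomentsError(f"gamma prior requires mean > 0, got mean={m}")
        shape = m * m / v
        scale = v / m
        return {"shape": shape, "scale": scale}, stats.gamma(shape, scale=scale), (0.0, math.inf)
    if family == "lognormal":
        if m <= 0:
            raise InfeasibleMomentsError(f"lognormal prior requires mean > 0, got mean={m}")
        sdlog2 = math.log1p(v / (m * m))
        meanlog = math.log(m) - 0.5 * sdlog2
        sdlog = math.sqrt(sdlog2)
        return (
            {"meanlog": meanlog, "sdlog": sdlog},
            stats.lognorm(sdlog, scale=math.exp(meanlog)),
            (0.0, math.inf),
        )
    if family == "uniform":
        half = math.sqrt(3.0) * s
        a, b = m - half, m + half
        return {"lo": a, "hi": b}, stats.uniform(a, b - a), (a, b)
    raise ValueError(f"unknown prior family {family!r}")


def fit_prior(spec: PriorSpec) -> FittedPrior:
    """Fit a prior by moment matching.

    The fitted parameters reproduce ``spec.mean`` and ``spec.se`` exactly
    (up to floating point).  ``spec.se == 0`` yields a flagged point-mass
    prior.  Quantile constraints, if supplied, are evaluated and reported
    in ``quantile_diagnostics`` as ``(p, target, achieved)`` triples.

    Raises
    ------
    InfeasibleMomentsError
        If the moments are unattainable for the family, naming the
        violated inequality.
    """
    m, s = float(spec.mean), float(spec.se)
    if s <= _DEGENERATE_TOL * max(abs(m), 1.0):
        if spec.family == "beta" and not 0.0 <= m <= 1.0:
            raise InfeasibleMomentsError(f"beta prior requires mean in [0, 1], got mean={m}")
        diags = tuple((p, v, m) for p, v in (spec.quantiles or ()))
        return FittedPrior(
            family=spec.family, params={"location": m}, mean=m, se=0.0,
            support=(m, m), degenerate=True, quantile_diagnostics=diags,
        )
    params, dist, support = _moment_params(spec.family, m, s)
    diags = tuple((p, v, float(dist.ppf(p))) for p, v in (spec.quantiles or ()))
    return FittedPrior(
        family=spec.family, params=params,
        mean=float(dist.mean()), se=float(dist.std()),
        support=support, quantile_diagnostics=diags, dist=dist,
    )


def fit_prior_from_quantiles(
    family: str,
    quantiles: Sequence[tuple[float, float]],
) -> FittedPrior:
    """Fit a prior so that two stated quantiles are matched.

    Secondary fitting route for the common case where only an interval is
    reported (e.g. a 95% CI) rather than a mean and SE.  The (mean, se)
    pair whose moment-matched member of ``family`` reproduces the two
    quantiles is found numerically.

    Parameters
    ----------
    family : str
        Prior family.
    quantiles : two (probability, value) pairs
        e.g. ``[(0.025, 0.04), (0.975, 0.19)]``.
    """
    qs = sorted((float(p), float(v)) for p, v in quantiles)
    if len(qs) != 2:
        raise ValueError("quantile fitting requires exactly two (p, value) pairs")
    (p1, q1), (p2, q2) = qs
    if not (0 < p1 < p2 < 1) or q2 <= q1:
        raise ValueError("quantile pairs must have increasing probabilities and values")

    # Normal-approximation starting point.
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    s0 = (q2 - q1) / (z2 - z1)
    m0 = q1 - z1 * s0

    def unpack(theta: np.ndarray) -> tuple[float, float]:
        if family == "beta":
            mean = 1.0 / (1.0 + math.exp(-theta[0]))  # logit scale keeps mean in (0,1)
            cap = math.sqrt(mean * (1 - mean))
            se = cap / (1.0 + math.exp(-theta[1]))  # se in (0, cap)
            return mean, se
        return float(theta[0]), math.exp(theta[1])

    if family == "beta":
        m0 = min(max(m0, 1e-6), 1 - 1e-6)
        cap = math.sqrt(m0 * (1 - m0))
        s0 = min(max(s0, 1e-9), 0.999 * cap)
        theta0 = np.array([math.log(m0 / (1 - m0)), math.log(s0 / (cap - s0))])
    else:
        if family in ("gamma", "lognormal"):
            m0 = max(m0, 1e-9)
        theta0 = np.array([m0, math.log(max(s0, 1e-12))])

    def residual(theta: np.ndarray) -> np.ndarray:
        mean, se = unpack(theta)
        try:
            _, dist, _ = _moment_params(family, mean, se)
        except InfeasibleMomentsError:
            return np.array([1e6, 1e6])
        return np.array([dist.ppf(p1) - q1, dist.ppf(p2) - q2])

    sol = optimize.least_squares(residual, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    scale = max(abs(q1), abs(q2), 1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6 * scale:
        raise ValueError(
            f"could not match quantiles {qs} with a {family} prior "
            f"(residual {np.max(np.abs(sol.fun)):.3g})"
        )
    mean, se = unpack(sol.x)
    return fit_prior(PriorSpec(family=family, mean=mean, se=se, quantiles=tuple(qs)))
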