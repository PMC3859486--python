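"""Ability (fitness) distributions for the agent population.

Abilities are probabilities in (0, 1]: agent i guesses the environment
state on its own with probability ``a_i``.  Four families are supported —
constant, normal, log-normal and bounded Pareto (an algebraic, fat-tailed
law) — all moment-matched to a requested mean and variance so that runs
with different shapes are comparable.

The bounded Pareto has density proportional to ``x**(-alpha-1)`` on
``[L, H]``:

    f(x) = alpha * L**alpha * x**(-alpha-1) / (1 - (L/H)**alpha)

Sampling uses the inverse-transform method, and fitting adjusts
``(alpha, L)`` at fixed ``H`` so the closed-form first two moments hit the
targets.  Unlike naively truncating an unbounded power law at H, the
bounded form has no probability atom at the upper limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "AbilitySpec",
    "bounded_pareto_pdf",
    "bounded_pareto_sample",
    "bounded_pareto_cdf",
    "bounded_pareto_moment",
    "fit_bounded_pareto",
    "sample_abilities",
    "ParetoFitError",
]

FAMILIES = ("constant", "normal", "lognormal", "bounded_pareto")


class ParetoFitError(RuntimeError):
    """Raised when no (alpha, L) reproduces the requested moments."""


@dataclass
class AbilitySpec:
    """Descriptor of an ability distribution.

    For ``bounded_pareto``, either give ``alpha`` and ``lower`` explicitly
    or leave them ``None`` to have them fitted to ``target_mean`` /
    ``target_variance`` with the upper limit fixed at ``upper``.
    """

    family: str = "bounded_pareto"
    target_mean: float = 0.25
    target_variance: float = 1.0 / 48.0
    alpha: Optional[float] = None
    lower: Optional[float] = None
    upper: float = 1.0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"ability family must be one of {FAMILIES}, got {self.family!r}"
            )
        if not 0.0 < self.target_mean < 1.0:
            raise ValueError(f"target_mean must lie in (0, 1), got {self.target_mean}")
        if self.target_variance < 0.0:
            raise ValueError(f"target_variance must be >= 0, got {self.target_variance}")
        if not 0.0 < self.upper <= 1.0:
            raise ValueError(f"upper must lie in (0, 1], got {self.upper}")
        if (self.alpha is None) != (self.lower is None):
            raise ValueError("alpha and lower must be given together or both fitted")


def _check_pareto_params(alpha: float, low: float, high: float) -> None:
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not 0.0 < low < high:
        raise ValueError(f"need 0 < L < H, got L={low}, H={high}")


def bounded_pareto_pdf(x, alpha: float, low: float, high: float):
    """Density of the bounded Pareto on [L, H] (0 outside)."""
    _check_pareto_params(alpha, low, high)
    x = np.asarray(x, dtype=float)
    norm = alpha * low**alpha / (1.0 - (low / high) ** alpha)
    out = np.where((x >= low) & (x <= high), norm * x ** (-alpha - 1.0), 0.0)
    return out if out.ndim else float(out)


def bounded_pareto_cdf(x, alpha: float, low: float, high: float):
    """CDF of the bounded Pareto on [L, H]."""
    _check_pareto_params(alpha, low, high)
    x = np.clip(np.asarray(x, dtype=float), low, high)
    out = (1.0 - (low / x) ** alpha) / (1.0 - (low / high) ** alpha)
    return out if out.ndim else float(out)


def bounded_pareto_sample(alpha: float, low: float, high: float, u):
    """Inverse-transform sample: maps uniform u in [0, 1] to [L, H].

    Monotone in u, with u=0 -> L and u=1 -> H.
    """
    _check_pareto_params(alpha, low, high)
    u = np.asarray(u, dtype=float)
    ha = high**alpha
    la = low**alpha
    out = (-(u * ha - u * la - ha) / (ha * la)) ** (-1.0 / alpha)
    return out if out.ndim else float(out)


def bounded_pareto_moment(order: float, alpha: float, low: float, high: float) -> float:
    """Raw moment E[X**order] of the bounded Pareto, in closed form.

    The integral has a removable singularity at ``order == alpha`` where the
    logarithmic limit form is used instead.
    """
    _check_pareto_params(alpha, low, high)
    c = alpha * low**alpha / (1.0 - (low / high) ** alpha)
    if abs(alpha - order) < 1e-9:
        return c * math.log(high / low)
    m = order - alpha
    return c * (high**m - low**m) / m


def _pareto_mean_var(alpha: float, low: float, high: float) -> tuple[float, float]:
    m1 = bounded_pareto_moment(1, alpha, low, high)
    m2 = bounded_pareto_moment(2, alpha, low, high)
    return m1, m2 - m1 * m1


def fit_bounded_pareto(
    target_mean: float,
    target_variance: float,
    high: float = 1.0,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Find (alpha, L) whose bounded Pareto on [L, high] has the target moments.

    Deterministic: a fixed starting point and a derivative-based least-squares
    solve on the closed-form moment residuals, so repeated fits give identical
    parameters.  Raises :class:`ParetoFitError` (with the residuals) if the
    targets cannot be met to within 1e-6.
    """
    if not 0.0 < target_mean < high:
        raise ParetoFitError(
            f"target mean {target_mean} outside the feasible range (0, {high})"
        )
    if target_variance <= 0.0:
        raise ParetoFitError(
            "a non-degenerate bounded Pareto has strictly positive variance; "
            f"target_variance={target_variance} is infeasible"
        )

    def residuals(z):
        alpha = math.exp(z[0])
        low = high / (1.0 + math.exp(-z[1]))  # logistic: 0 < L < H
        mean, var = _pareto_mean_var(alpha, low, high)
        return [mean - target_mean, var - target_variance]

    # Fixed start: moderate tail exponent, lower limit well below the mean.
    z0 = [math.log(1.5), math.log((0.5 * target_mean) / (high - 0.5 * target_mean))]
    sol = optimize.least_squares(residuals, z0, xtol=tol, ftol=tol, gtol=tol)
    alpha = math.exp(sol.x[0])
    low = high / (1.0 + math.exp(-sol.x[1]))
    mean, var = _pareto_mean_var(alpha, low, high)
    if abs(mean - target_mean) > 1e-6 or abs(var - target_variance) > 1e-6:
        raise ParetoFitError(
            "bounded-Pareto fit failed: residuals "
            f"mean {mean - target_mean:+.3e}, variance {var - target_variance:+.3e}"
        )
    return alpha, low


def _rejection_sample(draw, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw until n values fall inside (0, 1]; shape-preserving truncation."""
    out = np.empty(0)
    for _ in range(1000):
        batch = draw(max(n - out.size, 16), rng)
        batch = batch[(batch > 0.0) & (batch <= 1.0)]
        out = np.concatenate([out, batch])
        if out.size >= n:
            return out[:n]
    raise RuntimeError("rejection sampling failed to produce in-range abilities")


def sample_abilities(spec: AbilitySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n abilities in (0, 1] according to ``spec``.

    constant      -- every agent gets ``target_mean``.
    normal        -- N(mean, var), redrawn until inside (0, 1].
    lognormal     -- underlying normal parameters chosen so the *untruncated*
                     log-normal has the target mean and variance, then redrawn
                     until inside (0, 1].
    bounded_pareto-- (alpha, L) fitted (or taken from the spec) and sampled by
                     inverse transform; support [L, H] needs no rejection.
    """
    spec.validate()
    if n < 0:
        raise ValueError("n must be non-negative")
    mean, var = spec.target_mean, spec.target_variance
    if spec.family == "constant":
        return np.full(n, mean)
    if spec.family == "normal":
        sd = math.sqrt(var)
        return _rejection_sample(lambda k, g: g.normal(mean, sd, k), n, rng)
    if spec.family == "lognormal":
        sigma2 = math.log(1.0 + var / mean**2)
        mu = math.log(mean) - sigma2 / 2.0
        sd = math.sqrt(sigma2)
        return _rejection_sample(lambda k, g: g.lognormal(mu, sd, k), n, rng)
    # bounded_pareto
    if spec.alpha is not None:
        alpha, low = spec.alpha, spec.lower
        _check_pareto_params(alpha, low, spec.upper)
    else:
        alpha, low = fit_bounded_pareto(mean, var, spec.upper)
    return bounded_pareto_sample(alpha, low, spec.upper, rng.random(n))
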