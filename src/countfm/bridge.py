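"""Conditional binomial bridge between count vectors.

Given endpoints x0, x1 the bridge interpolates coordinatewise:

    X_t(i) = x0(i) + sgn(x1(i) - x0(i)) * B_t(i),
    B_t(i) ~ Binomial(|x1(i) - x0(i)|, t),

independently across coordinates given the endpoints, so the path pins both
endpoints and every intermediate state is a count vector lying between x0 and
x1.  The Kolmogorov forward equation for this path is solved in closed form by
the conditional rates

    birth_i(x) = (x1(i) - x(i))_+ / (1 - t),
    death_i(x) = (x(i) - x1(i))_+ / (1 - t),

with 1 - t regularized to 1 - t + eps_t to avoid blow-up near t = 1.  The
finite-difference residual of the forward equation is exposed as a test
oracle, and :class:`ConditionalRateOracle` packages the analytic rates behind
the same interface as a learned model for sampler tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpsilonConfig, RatePair, ValidationError, as_counts


@dataclass(frozen=True)
class BridgeState:
    """A count vector together with the bridge time it was drawn at."""

    x: np.ndarray
    t: float

    def __post_init__(self):
        x = as_counts(self.x)
        t = float(self.t)
        if not 0.0 <= t <= 1.0:
            raise ValidationError("t must lie in [0, 1]")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)


def _check_pair(x0, x1):
    x0 = as_counts(x0)
    x1 = as_counts(x1)
    if x0.shape[-1] != x1.shape[-1]:
        raise ValidationError("x0 and x1 dimensions differ")
    return x0, x1


def sample_bridge(x0, x1, t: float, seed=None, rng=None) -> BridgeState:
    """Draw X_t from the conditional bridge given endpoints.

    Accepts single vectors or aligned batches.  Equal coordinates consume no
    randomness, so equal and unequal endpoints stay on the same RNG stream.
    """
    x0, x1 = _check_pair(x0, x1)
    if x0.shape[0] not in (1, x1.shape[0]) and x1.shape[0] != 1:
        raise ValidationError("batch sizes of x0 and x1 are incompatible")
    if not 0.0 <= t <= 1.0:
        raise ValidationError("t must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    x0b, x1b = np.broadcast_arrays(x0, x1)
    diff = x1b - x0b
    gap = np.abs(diff)
    b = np.zeros_like(gap)
    nz = gap > 0
    if np.any(nz):
        b[nz] = rng.binomial(gap[nz], t)
    x = x0b + np.sign(diff) * b
    return BridgeState(x, t)


def bridge_marginal_pmf(x0_i: int, x1_i: int, t: float):
    """Exact one-coordinate bridge pmf.

    Returns (support, pmf) where support runs from min(x0_i, x1_i) to
    max(x0_i, x1_i) inclusive and pmf sums to 1.
    """
    x0_i, x1_i = int(x0_i), int(x1_i)
    if x0_i < 0 or x1_i < 0:
        raise ValidationError("counts must be nonnegative")
    if not 0.0 <= t <= 1.0:
        raise ValidationError("t must lie in [0, 1]")
    lo, hi = min(x0_i, x1_i), max(x0_i, x1_i)
    support = np.arange(lo, hi + 1)
    n = hi - lo
    if n == 0:
        return support, np.array([1.0])
    k = np.abs(support - x0_i)  # number of jumps taken toward x1
    # scipy's binom.pmf overflows internally for denormal p; the clamp is
    # far below any representable change in the pmf itself
    pmf = stats.binom.pmf(k, n, min(max(t, 1e-12), 1.0 - 1e-12))
    if t == 0.0 or t == 1.0:
        pmf = np.where(support == (x0_i if t == 0.0 else x1_i), 1.0, 0.0)
    return support, pmf


def conditional_rates(x, x1, t: float, eps: EpsilonConfig | float = EpsilonConfig()) -> RatePair:
    """Closed-form conditional birth/death rates of the bridge toward x1."""
    x, x1 = _check_pair(x, x1)
    if not 0.0 <= t <= 1.0:
        raise ValidationError("t must lie in [0, 1]")
    eps_t = eps if isinstance(eps, float) else eps.eps_t
    denom = 1.0 - t + eps_t
    diff = x1 - x
    birth = np.maximum(diff, 0) / denom
    death = np.maximum(-diff, 0) / denom
    return RatePair(birth.astype(float), death.astype(float))


def forward_equation_residual(x0_i: int, x1_i: int, t: float, dt: float = 1e-5) -> float:
    """Max |d/dt pmf - (influx - outflux)| over the bridge support.

    Central finite differences of the exact binomial pmf versus the mass
    balance implied by the unregularized conditional rates; a pure test
    oracle for the forward-equation property.
    """
    if not (0.0 < t < 1.0) or not (0.0 < t - dt and t + dt < 1.0):
        raise ValidationError("need 0 < t-dt < t+dt < 1")
    support, p = bridge_marginal_pmf(x0_i, x1_i, t)
    _, p_lo = bridge_marginal_pmf(x0_i, x1_i, t - dt)
    _, p_hi = bridge_marginal_pmf(x0_i, x1_i, t + dt)
    dp_dt = (p_hi - p_lo) / (2.0 * dt)

    def rate(x):
        denom = 1.0 - t
        return (max(x1_i - x, 0) / denom, max(x - x1_i, 0) / denom)

    pmf = dict(zip(support.tolist(), p.tolist()))
    residual = 0.0
    for idx, x in enumerate(support.tolist()):
        lam_m, _ = rate(x - 1)
        _, mu_p = rate(x + 1)
        lam_x, mu_x = rate(x)
        influx = lam_m * pmf.get(x - 1, 0.0) + mu_p * pmf.get(x + 1, 0.0)
        outflux = (lam_x + mu_x) * pmf.get(x, 0.0)
        residual = max(residual, abs(dp_dt[idx] - (influx - outflux)))
    return residual


class ConditionalRateOracle:
    """Analytic-rate stand-in for a learned model, steering toward fixed x1.

    Exposes the same ``rates(x, t, y)`` interface the sampler consumes; used
    to validate the sampler independently of training.
    """

    def __init__(self, x1, eps: EpsilonConfig = EpsilonConfig()):
        self.x1 = as_counts(x1)
        self.eps = eps

    def rates(self, x, t, y=None) -> RatePair:
        return conditional_rates(x, self.x1, float(t), self.eps)
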