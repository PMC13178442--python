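"""Forward simulation of the learned birth-death process.

The sampler integrates the jump process from t = eps_t to t = 1 - eps_t with a
first-order local-jump scheme: with K steps of size Delta = (1 - 2 eps_t) / K
and total per-coordinate rate r_i = birth_i + death_i,

    p_stay  = exp(-r_i Delta),
    p_birth = (1 - exp(-r_i Delta)) * birth_i / (r_i + eps_r),
    p_death = (1 - exp(-r_i Delta)) * death_i / (r_i + eps_r),

one of {stay, +1, -1} is sampled independently per coordinate and all
coordinate updates are applied simultaneously.  States therefore stay
nonnegative integer vectors throughout (the x * beta death parameterization
makes death at zero structurally impossible) and change by at most one unit
per coordinate per step.  Rates are evaluated at the left endpoint of each
step (explicit Euler convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix, EpsilonConfig, RatePair, ValidationError, as_counts
from .rate_model import GuidanceConfig, cfg_rates, predict_rates


@dataclass(frozen=True)
class SamplerConfig:
    K: int = 500
    eps: EpsilonConfig = field(default_factory=EpsilonConfig)
    guidance: GuidanceConfig | None = None
    record_trajectory: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")


@dataclass
class Trajectory:
    times: list
    states: list  # CountMatrix snapshots aligned with times


def step_probs(rates: RatePair, delta: float, eps_r: float = 1e-8):
    """Per-coordinate (p_stay, p_birth, p_death) for one step of size delta."""
    if delta <= 0:
        raise ValidationError("delta must be positive")
    r = rates.total
    p_stay = np.exp(-r * delta)
    jump = 1.0 - p_stay
    denom = r + eps_r
    p_birth = jump * rates.birth / denom
    p_death = jump * rates.death / denom
    return p_stay, p_birth, p_death


def _eval_rates(model, x, t, y, guidance):
    if hasattr(model, "rates"):
        return model.rates(x, t, y)
    use_cfg = (
        guidance is not None
        and getattr(model, "cond_spec", None) is not None
        and guidance.w != 1.0
    )
    if not use_cfg:
        return predict_rates(model, x, t, y=y)
    uncond = predict_rates(model, x, t, y=None)
    if guidance.w == 0.0:
        return uncond
    cond = predict_rates(model, x, t, y=y)
    return cfg_rates(cond, uncond, guidance.w)


def simulate(model, x_init, y=None, config: SamplerConfig = SamplerConfig()):
    """Simulate the birth-death process forward from the source states.

    model is a trained :class:`RateModel` or any object exposing
    ``rates(x, t, y) -> RatePair`` (e.g. the analytic bridge oracle).
    Returns the terminal CountMatrix, or (CountMatrix, Trajectory) when
    configured to record.
    """
    x = as_counts(x_init).copy()
    rng = np.random.default_rng(config.seed)
    eps_t = config.eps.eps_t
    delta = (1.0 - 2.0 * eps_t) / config.K
    traj = Trajectory([eps_t], [CountMatrix(x.copy())]) if config.record_trajectory else None
    nfe = 0
    for k in range(config.K):
        t_k = eps_t + k * delta
        rates = _eval_rates(model, x, t_k, y, config.guidance)
        nfe += 2 if (config.guidance is not None and config.guidance.w not in (0.0, 1.0)
                     and getattr(model, "cond_spec", None) is not None) else 1
        if not (np.all(np.isfinite(rates.birth)) and np.all(np.isfinite(rates.death))):
            raise RuntimeError(f"non-finite rates at step {k} (t={t_k:.5f})")
        p_stay, p_birth, p_death = step_probs(rates, delta, config.eps.eps_r)
        p_death = np.where(x > 0, p_death, 0.0)  # hard floor of the state space
        u = rng.random(size=x.shape)
        x = x + (u < p_birth).astype(np.int64) - (
            (u >= p_birth) & (u < p_birth + p_death)
        ).astype(np.int64)
        if traj is not None:
            traj.times.append(t_k + delta)
            traj.states.append(CountMatrix(x.copy()))
    result = CountMatrix(x)
    if traj is not None:
        return result, traj
    return result
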