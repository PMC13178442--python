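"""Simulation-free training of the rate field.

Each step draws endpoint pairs from the configured coupling, a time
t ~ Uniform[eps_t, 1-eps_t], and a bridge state x ~ p_t(.|x0, x1), then
regresses the model's birth and death rates onto the closed-form conditional
rates under the generalized-KL score

    l(u, v) = v - u log(v + eps_l),

summed over coordinates and both heads and averaged over the batch.  Because
l(u, .) is a proper score with population minimizer v = u, fitting the
conditional rates drives the model toward the marginal transition rates of the
mixture-of-bridges path.  Optimization is Adam with global-norm gradient
clipping (early steps can see very large analytic targets near t = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import EpsilonConfig, ValidationError, as_counts
from .coupling import (
    ot_coupling,
    poisson_cost_matrix,
    group_restricted_pairs,
)
from .rate_model import RateModel, _sigmoid, _softplus, save_checkpoint


@dataclass(frozen=True)
class TrainConfig:
    steps: int = 40000
    batch_size: int = 256
    learning_rate: float = 1e-3
    eps: EpsilonConfig = field(default_factory=EpsilonConfig)
    coupling: str = "independent"  # independent | ot | group_ot
    seed: int = 0
    condition_dropout_prob: float = 0.1
    grad_clip: float = 10.0
    lr_schedule: str = "constant"  # constant | cosine decay to 1% of learning_rate
    ema_decay: float = 0.999  # exponential moving average of weights; 0 disables
    ot_sample_pairs: bool = True  # False: use the optimal permutation directly
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.steps < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("invalid TrainConfig")
        if self.coupling not in ("independent", "ot", "group_ot"):
            raise ValidationError(f"unknown coupling {self.coupling!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValidationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValidationError("ema_decay must be in [0, 1)")


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    birth_term: float
    death_term: float


def pointwise_loss(u_target: float, v_model: float, eps_l: float = 1e-6) -> float:
    """Generalized-KL score l(u, v) = v - u log(v + eps_l); minimized at v = u."""
    if np.any(np.asarray(u_target) < 0) or np.any(np.asarray(v_model) < 0):
        raise ValidationError("rates must be nonnegative")
    return v_model - u_target * np.log(v_model + eps_l)


def batch_loss(model: RateModel, pairs, y=None, eps: EpsilonConfig = EpsilonConfig(),
               seed: int = 0, null_mask=None, rng=None, return_grads: bool = False):
    """Single-sample estimate of the training objective on a batch of pairs.

    pairs is (X0, X1) aligned arrays.  Draws one t per pair and one bridge
    state per pair; returns a LossBreakdown, optionally with parameter
    gradients (used by :func:`train`).
    """
    x0, x1 = pairs
    x0 = as_counts(x0)
    x1 = as_counts(x1)
    if x0.shape != x1.shape:
        raise ValidationError("paired endpoint batches must be aligned")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, d = x0.shape
    t = rng.uniform(eps.eps_t, 1.0 - eps.eps_t, size=n)
    # coordinatewise bridge draw with per-row t
    gap = np.abs(x1 - x0)
    b = np.zeros_like(gap)
    nz = gap > 0
    if nz.any():
        b[nz] = rng.binomial(gap[nz], np.broadcast_to(t[:, None], gap.shape)[nz])
    x = x0 + np.sign(x1 - x0) * b

    denom = (1.0 - t + eps.eps_t)[:, None]
    diff = x1 - x
    u_birth = np.maximum(diff, 0) / denom
    u_death = np.maximum(-diff, 0) / denom

    s, cache = model.forward(x, t, y=y, null_mask=null_mask, cache=return_grads)
    sb, sd = s[:, :d], s[:, d:]
    v_birth = _softplus(sb)
    beta = _softplus(sd)
    xf = x.astype(float)
    v_death = xf * beta

    lb = v_birth - u_birth * np.log(v_birth + eps.eps_l)
    ld = v_death - u_death * np.log(v_death + eps.eps_l)
    birth_term = float(lb.sum(axis=1).mean())
    death_term = float(ld.sum(axis=1).mean())
    breakdown = LossBreakdown(birth_term + death_term, birth_term, death_term)
    if not return_grads:
        return breakdown

    dvb = (1.0 - u_birth / (v_birth + eps.eps_l)) / n
    dvd = (1.0 - u_death / (v_death + eps.eps_l)) / n
    ds = np.concatenate([dvb * _sigmoid(sb), dvd * xf * _sigmoid(sd)], axis=1)
    grads = model.backward(cache, ds)
    return breakdown, grads


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads, max_norm):
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
    return grads


def _draw_batch(data, b, rng):
    if callable(data):
        return as_counts(data(b, int(rng.integers(2**31))))
    arr = as_counts(data)
    idx = rng.integers(0, arr.shape[0], size=b)
    return arr[idx]


def train(model: RateModel, source, target, config: TrainConfig,
          covariates=None, source_labels=None, target_labels=None,
          group_map=None):
    """Train the rate model in place; returns (model, loss history).

    source may be a CountMatrix/array or a callable ``(n, seed) -> counts``
    (an inexhaustible source sampler).  For conditional training, covariates
    must align with the rows of ``target``; condition dropout replaces their
    embedding by the learned null embedding with the configured probability.
    """
    rng = np.random.default_rng(config.seed)
    history: list[LossBreakdown] = []
    target_arr = as_counts(target)
    if covariates is not None and model.cond_spec is None:
        raise ValidationError("covariates supplied but the model is unconditional")
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    opt = _Adam(model.params, config.learning_rate)
    ema = ({k: v.copy() for k, v in model.params.items()}
           if config.ema_decay > 0 else None)
    b = config.batch_size
    if config.coupling == "group_ot" and (
            callable(source) or source_labels is None or target_labels is None
            or group_map is None):
        raise ValidationError(
            "group_ot coupling needs an in-memory source with aligned "
            "source_labels, target_labels, and a group_map")
    for step in range(config.steps):
        if config.coupling == "group_ot":
            src_arr = as_counts(source)
            sidx = rng.integers(0, src_arr.shape[0], size=b)
            x0b = src_arr[sidx]
            lab0 = np.asarray(source_labels)[sidx]
        else:
            x0b = _draw_batch(source, b, rng)
        tidx = rng.integers(0, target_arr.shape[0], size=b)
        x1b = target_arr[tidx]
        y = None
        if covariates is not None:
            y = np.asarray(covariates)[tidx]
        if config.coupling == "independent":
            # the uniform index draws above already realize the product coupling
            pairs = (x0b, x1b)
        elif config.coupling == "ot":
            cost = poisson_cost_matrix(x0b, x1b, config.eps.eps_c)
            plan = ot_coupling(cost)
            if config.ot_sample_pairs:
                i0, i1 = _plan_pair_indices(plan, rng)
            else:
                rows, cols = np.nonzero(plan.gamma)
                order = np.argsort(rows)
                i0, i1 = rows[order], cols[order]
            pairs = (x0b[i0], x1b[i1])
            if y is not None:
                y = y[i1]
        else:  # group_ot
            pairs0, pairs1, _ = group_restricted_pairs(
                x0b, lab0, x1b, np.asarray(target_labels)[tidx], group_map,
                eps_c=config.eps.eps_c, seed=int(rng.integers(2**31)),
            )
            pairs = (pairs0, pairs1)
            y = None
        null_mask = None
        if y is not None and config.condition_dropout_prob > 0:
            null_mask = rng.random(pairs[0].shape[0]) < config.condition_dropout_prob
        breakdown, grads = batch_loss(
            model, pairs, y=y, eps=config.eps, rng=rng,
            null_mask=null_mask, return_grads=True,
        )
        if not np.isfinite(breakdown.total):
            raise RuntimeError(
                f"non-finite loss at step {step}: {breakdown} "
                f"(param norms: { {k: float(np.abs(v).max()) for k, v in model.params.items()} })"
            )
        _clip_grads(grads, config.grad_clip)
        if config.lr_schedule == "cosine":
            lo = 0.01 * config.learning_rate
            opt.lr = lo + 0.5 * (config.learning_rate - lo) * (
                1.0 + np.cos(np.pi * step / config.steps))
        opt.step(model.params, grads)
        if ema is not None:
            # warmup-capped decay: tracks tightly early, averages late
            d = min(config.ema_decay, (1 + step) / (10 + step))
            for k, v in model.params.items():
                ema[k] = d * ema[k] + (1 - d) * v
        history.append(breakdown)
        if ckpt_dir is not None and config.checkpoint_every > 0 and (
                (step + 1) % config.checkpoint_every == 0):
            save_checkpoint(model, ckpt_dir / f"step{step + 1:07d}.npz",
                            extra={"step": step + 1})
    if ema is not None and config.steps > 0:
        for k in model.params:
            model.params[k] = ema[k]
    return model, history


def _plan_pair_indices(plan, rng):
    probs = plan.gamma.reshape(-1)
    probs = probs / probs.sum()
    flat = rng.choice(plan.B * plan.B, size=plan.B, p=probs)
    return np.divmod(flat, plan.B)
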