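"""Learnable birth-death rate field.

A single MLP with shared hidden layers and separate output channels maps
(x, t[, y]) to d nonnegative birth rates and d nonnegative death coefficients.
Death rates are parameterized multiplicatively, mu = x * beta(x, t), so a
coordinate sitting at zero can structurally never die, for any parameter
values.  Nonnegativity of both heads is enforced by a softplus map.

Conditioning (optional) embeds real covariates through a learned linear map,
or categorical labels through an embedding table; a learned null embedding
replaces the covariate embedding for dropped-out rows during training and for
unconditional prediction, enabling classifier-free guidance at sampling time
via :func:`cfg_rates`.

The network, its backward pass, and the Adam updates are implemented directly
on numpy arrays: the models used here are small (width ~32-128) and CPU-bound
matrix products dominate, so a tensor framework buys nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .containers import RatePair, ValidationError, as_counts

logger = logging.getLogger(__name__)

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _selu(z):
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))


def _selu_grad(z):
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))


def _softplus(z):
    return np.logaddexp(0.0, z)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass(frozen=True)
class ArchConfig:
    """Backbone hyperparameters.

    hidden: widths of the shared hidden layers.
    time_freqs: number of sinusoidal time-embedding frequencies (powers of 2).
    log1p: feed log1p-scaled counts to the network instead of raw counts
        (recommended for high-count regimes such as scRNA).
    cond_embed_dim: width of the covariate / null embedding when conditioning.
    """

    hidden: tuple = (32, 32)
    time_freqs: int = 4
    log1p: bool = False
    cond_embed_dim: int = 8

    def __post_init__(self):
        if len(self.hidden) < 1 or any(int(h) < 1 for h in self.hidden):
            raise ValidationError("hidden must be a nonempty tuple of widths >= 1")
        if self.time_freqs < 1 or self.cond_embed_dim < 1:
            raise ValidationError("time_freqs and cond_embed_dim must be >= 1")
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))


@dataclass(frozen=True)
class GuidanceConfig:
    """Classifier-free guidance: scale w >= 0 and training dropout probability."""

    w: float = 1.0
    condition_dropout_prob: float = 0.1

    def __post_init__(self):
        if self.w < 0:
            raise ValidationError("guidance scale w must be >= 0")
        if not 0.0 <= self.condition_dropout_prob <= 1.0:
            raise ValidationError("condition_dropout_prob must lie in [0, 1]")


class RateModel:
    """MLP rate field with parameters stored as a flat name -> array dict."""

    def __init__(self, d: int, arch: ArchConfig, cond_spec=None, seed: int = 0):
        if d < 1:
            raise ValidationError("d must be >= 1")
        if cond_spec is not None:
            kind, size = cond_spec
            if kind not in ("real", "categorical") or int(size) < 1:
                raise ValidationError(
                    "cond_spec must be None, ('real', dim) or ('categorical', n)"
                )
            cond_spec = (kind, int(size))
        self.d = int(d)
        self.arch = arch
        self.cond_spec = cond_spec
        self.params: dict[str, np.ndarray] = {}
        self._init_params(seed)

    # ---- initialization -------------------------------------------------
    def _input_dim(self) -> int:
        dim = self.d + 2 * self.arch.time_freqs + 1
        if self.cond_spec is not None:
            dim += self.arch.cond_embed_dim
        return dim

    def _init_params(self, seed: int):
        rng = np.random.default_rng(seed)
        sizes = [self._input_dim(), *self.arch.hidden]
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            self.params[f"W{i}"] = rng.normal(0, 1 / np.sqrt(fan_in), (fan_in, sizes[i + 1]))
            self.params[f"b{i}"] = np.zeros(sizes[i + 1])
        fan_in = sizes[-1]
        self.params["Wout"] = rng.normal(0, 1 / np.sqrt(fan_in), (fan_in, 2 * self.d))
        self.params["bout"] = np.zeros(2 * self.d)
        if self.cond_spec is not None:
            kind, size = self.cond_spec
            e = self.arch.cond_embed_dim
            if kind == "real":
                self.params["Wy"] = rng.normal(0, 1 / np.sqrt(size), (size, e))
                self.params["by"] = np.zeros(e)
            else:
                self.params["Emb"] = rng.normal(0, 1.0, (size, e))
            self.params["z_null"] = rng.normal(0, 1.0, e)

    # ---- forward --------------------------------------------------------
    def _time_embed(self, t, n):
        t = np.broadcast_to(np.asarray(t, dtype=float).reshape(-1), (n,))
        freqs = 2.0 ** np.arange(self.arch.time_freqs)
        ang = 2.0 * np.pi * t[:, None] * freqs[None, :]
        return np.concatenate([t[:, None], np.sin(ang), np.cos(ang)], axis=1)

    def _cond_embed(self, y, n, null_mask):
        z_null = self.params["z_null"]
        extra = {}
        if y is None:
            z = np.tile(z_null, (n, 1))
            null_rows = np.ones(n, dtype=bool)
            extra["y"] = None
        else:
            kind, size = self.cond_spec
            if kind == "real":
                y = np.asarray(y, dtype=float)
                if y.ndim == 1:
                    y = y[:, None]
                if y.shape != (n, size):
                    raise ValidationError(f"covariates must have shape ({n}, {size})")
                z = y @ self.params["Wy"] + self.params["by"]
            else:
                y = np.asarray(y).reshape(-1).astype(int)
                if y.shape[0] != n or y.min() < 0 or y.max() >= size:
                    raise ValidationError("categorical labels out of range")
                z = self.params["Emb"][y]
            null_rows = np.zeros(n, dtype=bool)
            if null_mask is not None:
                null_rows = np.asarray(null_mask, dtype=bool)
                z = np.where(null_rows[:, None], z_null[None, :], z)
            extra["y"] = y
        extra["null_rows"] = null_rows
        return z, extra

    def forward(self, x, t, y=None, null_mask=None, cache: bool = False):
        """Pre-softplus outputs s of shape (n, 2d); optionally a backprop cache."""
        x = as_counts(x)
        n = x.shape[0]
        if x.shape[1] != self.d:
            raise ValidationError(f"x has dimension {x.shape[1]}, model expects {self.d}")
        xf = np.log1p(x.astype(float)) if self.arch.log1p else x.astype(float)
        feats = [xf, self._time_embed(t, n)]
        cond_extra = None
        if self.cond_spec is not None:
            z, cond_extra = self._cond_embed(y, n, null_mask)
            feats.append(z)
        elif y is not None:
            raise ValidationError("model is unconditional but covariates were given")
        h = np.concatenate(feats, axis=1)
        activations = [h]
        preacts = []
        n_hidden = len(self.arch.hidden)
        for i in range(n_hidden):
            z = activations[-1] @ self.params[f"W{i}"] + self.params[f"b{i}"]
            preacts.append(z)
            activations.append(_selu(z))
        s = activations[-1] @ self.params["Wout"] + self.params["bout"]
        if not cache:
            return s, None
        return s, {"activations": activations, "preacts": preacts, "cond": cond_extra}

    def backward(self, cache, ds):
        """Gradients of a scalar loss with respect to all parameters.

        ds is dLoss/ds for the pre-softplus outputs produced with cache=True.
        """
        grads = {}
        activations, preacts = cache["activations"], cache["preacts"]
        grads["Wout"] = activations[-1].T @ ds
        grads["bout"] = ds.sum(axis=0)
        da = ds @ self.params["Wout"].T
        for i in reversed(range(len(self.arch.hidden))):
            dz = da * _selu_grad(preacts[i])
            grads[f"W{i}"] = activations[i].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            da = dz @ self.params[f"W{i}"].T
        if self.cond_spec is not None:
            e = self.arch.cond_embed_dim
            dz_cond = da[:, -e:]
            cond = cache["cond"]
            null_rows = cond["null_rows"]
            grads["z_null"] = dz_cond[null_rows].sum(axis=0)
            y = cond["y"]
            if y is not None:
                kind, size = self.cond_spec
                live = ~null_rows
                if kind == "real":
                    grads["Wy"] = y[live].T @ dz_cond[live]
                    grads["by"] = dz_cond[live].sum(axis=0)
                else:
                    g = np.zeros_like(self.params["Emb"])
                    np.add.at(g, y[live], dz_cond[live])
                    grads["Emb"] = g
        return grads

    def copy(self) -> "RateModel":
        clone = RateModel.__new__(RateModel)
        clone.d = self.d
        clone.arch = self.arch
        clone.cond_spec = self.cond_spec
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone


def init_rate_model(d: int, arch: ArchConfig | None = None, cond_spec=None, seed: int = 0) -> RateModel:
    """Build a seeded rate model; see :class:`ArchConfig` for knobs."""
    return RateModel(d, arch or ArchConfig(), cond_spec=cond_spec, seed=seed)


def predict_rates(model: RateModel, x, t, y=None) -> RatePair:
    """Evaluate birth rates and boundary-safe death rates mu = x * beta."""
    x = as_counts(x)
    s, _ = model.forward(x, t, y=y)
    d = model.d
    birth = _softplus(s[:, :d])
    beta = _softplus(s[:, d:])
    death = x.astype(float) * beta
    return RatePair(birth, death)


def cfg_rates(cond: RatePair, uncond: RatePair, w: float) -> RatePair:
    """Classifier-free guidance combination, clamped at zero from below.

    rate = uncond + w * (cond - uncond); w=0 recovers the unconditional
    rates and w=1 the conditional ones exactly.  Extrapolation (w>1) can
    produce negative values, which are clamped and counted in a debug log.
    """
    if w < 0:
        raise ValidationError("guidance scale w must be >= 0")
    if cond.birth.shape != uncond.birth.shape:
        raise ValidationError("cond and uncond rate shapes differ")
    if w == 0.0:
        return uncond
    if w == 1.0:
        return cond
    birth = uncond.birth + w * (cond.birth - uncond.birth)
    death = uncond.death + w * (cond.death - uncond.death)
    n_clamped = int((birth < 0).sum() + (death < 0).sum())
    if n_clamped:
        logger.debug("cfg_rates clamped %d negative guided rates to 0", n_clamped)
    return RatePair(np.maximum(birth, 0.0), np.maximum(death, 0.0))


# ---- checkpointing ------------------------------------------------------

def save_checkpoint(model: RateModel, path, extra: dict | None = None) -> None:
    """Single-archive checkpoint: parameters + architecture + metadata."""
    meta = {
        "d": model.d,
        "arch": {
            "hidden": list(model.arch.hidden),
            "time_freqs": model.arch.time_freqs,
            "log1p": model.arch.log1p,
            "cond_embed_dim": model.arch.cond_embed_dim,
        },
        "cond_spec": list(model.cond_spec) if model.cond_spec else None,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path) -> tuple[RateModel, dict]:
    """Inverse of :func:`save_checkpoint`; returns (model, extra metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    arch = ArchConfig(
        hidden=tuple(meta["arch"]["hidden"]),
        time_freqs=meta["arch"]["time_freqs"],
        log1p=meta["arch"]["log1p"],
        cond_embed_dim=meta["arch"]["cond_embed_dim"],
    )
    cond_spec = tuple(meta["cond_spec"]) if meta["cond_spec"] else None
    model = RateModel(meta["d"], arch, cond_spec=cond_spec, seed=0)
    model.params = params
    return model, meta["extra"]
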