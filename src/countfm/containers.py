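"""Shared containers and numerical-stability configuration.

All public functions in the package pass count populations around as
:class:`CountMatrix` (rows = samples, columns = coordinates) and transition
rates as :class:`RatePair`.  The four stability constants that regularize the
closed-form bridge rates, the log in the generalized-KL loss, the sampler's
outcome normalization, and the optimal-transport ground cost live together in
:class:`EpsilonConfig` so sensitivity studies touch a single object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _as_int_matrix(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{name} must be nonempty (n >= 1, d >= 1)")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.all(np.isfinite(arr)) or np.any(np.abs(arr - rounded) > 0):
            bad = np.argwhere(
                ~np.isfinite(arr) | (np.abs(arr - np.rint(arr)) > 0)
            )[0]
            raise ValidationError(
                f"{name} entry at row {bad[0]}, column {bad[1]} is not an integer"
            )
        arr = rounded.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        bad = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{name} entry at row {bad[0]}, column {bad[1]} is negative"
        )
    return arr


@dataclass(frozen=True)
class CountMatrix:
    """A batch of nonnegative integer count vectors.

    Parameters
    ----------
    values
        ``n x d`` array of nonnegative integers.
    row_names, col_names
        Optional sample / coordinate labels, preserved by the I/O layer.
    """

    values: np.ndarray
    row_names: tuple | None = None
    col_names: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", _as_int_matrix(self.values))
        if self.row_names is not None and len(self.row_names) != self.n:
            raise ValidationError("row_names length does not match n")
        if self.col_names is not None and len(self.col_names) != self.d:
            raise ValidationError("col_names length does not match d")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def as_counts(x) -> np.ndarray:
    """Coerce a CountMatrix or array-like into a validated int64 matrix."""
    if isinstance(x, CountMatrix):
        return x.values
    return _as_int_matrix(x)


@dataclass(frozen=True)
class RatePair:
    """Per-coordinate nonnegative birth and death rates (per unit time)."""

    birth: np.ndarray
    death: np.ndarray

    def __post_init__(self):
        birth = np.asarray(self.birth, dtype=float)
        death = np.asarray(self.death, dtype=float)
        if birth.shape != death.shape:
            raise ValidationError("birth and death must have identical shapes")
        if np.any(birth < 0) or np.any(death < 0):
            raise ValidationError("rates must be nonnegative")
        object.__setattr__(self, "birth", birth)
        object.__setattr__(self, "death", death)

    @property
    def total(self) -> np.ndarray:
        return self.birth + self.death


@dataclass(frozen=True)
class EpsilonConfig:
    """Numerical-stability constants.

    eps_t regularizes the 1-t denominator of the bridge rates (and bounds the
    time interval the trainer and sampler use to [eps_t, 1-eps_t]); eps_l
    shifts the log inside the generalized-KL loss; eps_r guards the sampler's
    division by the total jump rate; eps_c stabilizes the symmetric Poisson
    transport cost at zero counts.
    """

    eps_t: float = 1e-4
    eps_l: float = 1e-6
    eps_r: float = 1e-8
    eps_c: float = 1e-3

    def __post_init__(self):
        for name in ("eps_t", "eps_l", "eps_r", "eps_c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
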