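"""Endpoint couplings between source and target minibatches.

Training pairs (x0, x1) are drawn either independently (product of the two
empirical marginals) or from the exact minibatch optimal-transport plan under
the symmetric Poisson cost

    c(x, y) = sum_i x_i log((x_i+eps)/(y_i+eps)) + y_i log((y_i+eps)/(x_i+eps)),

the symmetrized generalized-KL divergence between count vectors.  For uniform
marginals on equal-size minibatches the OT problem always admits a permutation
optimum (Birkhoff), so the exact plan is computed by linear assignment rather
than an entropic approximation.  Group-restricted coupling runs OT separately
inside label-compatible source/target groups, which is how lineage structure
is respected when transporting between developmental populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import ValidationError, as_counts


@dataclass(frozen=True)
class CouplingPlan:
    """A B x B transport plan with uniform 1/B marginals."""

    gamma: np.ndarray

    def __post_init__(self):
        gamma = np.asarray(self.gamma, dtype=float)
        if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
            raise ValidationError("gamma must be a square matrix")
        if np.any(gamma < 0):
            raise ValidationError("gamma must be nonnegative")
        b = gamma.shape[0]
        if (np.abs(gamma.sum(axis=1) - 1.0 / b).max() > 1e-8
                or np.abs(gamma.sum(axis=0) - 1.0 / b).max() > 1e-8):
            raise ValidationError("gamma marginals must equal 1/B")
        object.__setattr__(self, "gamma", gamma)

    @property
    def B(self) -> int:
        return self.gamma.shape[0]

    def objective(self, cost: np.ndarray) -> float:
        return float((self.gamma * cost).sum())


def independent_pairs(batch0, batch1, seed: int):
    """Pair by independent uniform indexing into each batch (product coupling)."""
    x0 = as_counts(batch0)
    x1 = as_counts(batch1)
    rng = np.random.default_rng(seed)
    b = min(x0.shape[0], x1.shape[0])
    i0 = rng.integers(0, x0.shape[0], size=b)
    i1 = rng.integers(0, x1.shape[0], size=b)
    return x0[i0], x1[i1]


def poisson_cost_matrix(X0, X1, eps_c: float = 1e-3) -> np.ndarray:
    """Pairwise symmetric Poisson (symmetrized generalized-KL) cost matrix."""
    if eps_c <= 0:
        raise ValidationError("eps_c must be strictly positive")
    a = as_counts(X0).astype(float) + eps_c
    b = as_counts(X1).astype(float) + eps_c
    if a.shape[1] != b.shape[1]:
        raise ValidationError("X0 and X1 dimensions differ")
    la, lb = np.log(a), np.log(b)
    # c(x,y) = sum_i (x_i - y_i)(log(x_i+eps) - log(y_i+eps)) up to the eps shift
    # expanded so the whole B x B' matrix is three matrix products.
    cost = (
        (a * la).sum(axis=1)[:, None]
        + (b * lb).sum(axis=1)[None, :]
        - a @ lb.T
        - la @ b.T
    )
    # counts enter the formula without the eps shift in the leading factors;
    # correct: x log(x+e/y+e) + y log(y+e/x+e) = (x - y)(log(x+e) - log(y+e)).
    # With a = x + eps, b = y + eps the difference a - b equals x - y, so the
    # expansion above is exact.  Clamp tiny negative round-off.
    return np.maximum(cost, 0.0)


def ot_coupling(cost: np.ndarray) -> CouplingPlan:
    """Exact OT plan with uniform marginals via linear assignment."""
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValidationError("cost must be square (truncate minibatches first)")
    if not np.all(np.isfinite(cost)):
        raise ValidationError("cost matrix contains non-finite entries")
    b = cost.shape[0]
    rows, cols = linear_sum_assignment(cost)
    gamma = np.zeros((b, b))
    gamma[rows, cols] = 1.0 / b
    return CouplingPlan(gamma)


def sample_pairs_from_plan(plan: CouplingPlan, X0, X1, n_pairs: int, seed: int):
    """Draw endpoint pairs i.i.d. from the categorical distribution gamma."""
    x0 = as_counts(X0)
    x1 = as_counts(X1)
    b = plan.B
    if x0.shape[0] < b or x1.shape[0] < b:
        raise ValidationError("plan is larger than the supplied batches")
    rng = np.random.default_rng(seed)
    probs = plan.gamma.reshape(-1)
    probs = probs / probs.sum()
    flat = rng.choice(b * b, size=n_pairs, p=probs)
    i0, i1 = np.divmod(flat, b)
    return x0[i0], x1[i1]


def plan_as_permutation(plan: CouplingPlan, X0, X1):
    """Deterministic alternative to sampling: extract the optimal matching.

    Valid when the plan is a permutation (always true for plans produced by
    :func:`ot_coupling`).
    """
    x0 = as_counts(X0)
    x1 = as_counts(X1)
    rows, cols = np.nonzero(plan.gamma)
    if rows.size != plan.B:
        raise ValidationError("plan is not a permutation plan")
    order = np.argsort(rows)
    return x0[rows[order]], x1[cols[order]]


def group_restricted_pairs(X0, labels0, X1, labels1, group_map: dict,
                           eps_c: float = 1e-3, seed: int = 0):
    """OT pairing restricted to label-compatible groups.

    For each source label, exact OT is computed against the union of its
    allowed target labels; group sizes are equalized by seeded subsampling of
    the larger side before assignment.  Returns matched (x0, x1) pairs plus
    the aligned source labels.
    """
    x0 = as_counts(X0)
    x1 = as_counts(X1)
    labels0 = np.asarray(labels0)
    labels1 = np.asarray(labels1)
    rng = np.random.default_rng(seed)
    out0, out1, outl = [], [], []
    for lab in np.unique(labels0):
        if lab not in group_map:
            raise ValidationError(f"source group {lab!r} missing from group_map")
        allowed = group_map[lab]
        tmask = np.isin(labels1, np.asarray(list(allowed)))
        if not tmask.any():
            raise ValidationError(
                f"source group {lab!r} has no allowed targets present"
            )
        src = x0[labels0 == lab]
        tgt = x1[tmask]
        m = min(src.shape[0], tgt.shape[0])
        if src.shape[0] > m:
            src = src[rng.choice(src.shape[0], size=m, replace=False)]
        if tgt.shape[0] > m:
            tgt = tgt[rng.choice(tgt.shape[0], size=m, replace=False)]
        cost = poisson_cost_matrix(src, tgt, eps_c)
        plan = ot_coupling(cost)
        p0, p1 = plan_as_permutation(plan, src, tgt)
        out0.append(p0)
        out1.append(p1)
        outl.append(np.full(m, lab))
    return np.concatenate(out0), np.concatenate(out1), np.concatenate(outl)
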