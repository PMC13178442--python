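"""Sample-quality metrics and the seeded simulation benchmark.

Unconditional quality is measured by the 2-Wasserstein distance between
empirical distributions under the Euclidean ground metric (exact linear
assignment for equal-size clouds) and by the unbiased squared maximum mean
discrepancy with a Gaussian RBF kernel, with a median-heuristic bandwidth by
default.  Conditional generation against binned covariates is scored by
bin-weighted RMSEs of means, variances, and zero fractions, a Frobenius
discrepancy of off-diagonal covariance matrices, and a peak-to-background
contrast of the per-coordinate tuning curves.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .containers import CountMatrix, ValidationError, spawn_seeds
from .rate_model import ArchConfig, init_rate_model
from .sampler import SamplerConfig, simulate
from .synthetic import (
    default_mixture_spec,
    default_source_spec,
    sample_gamma_poisson_mixture,
    sample_uniform_grid,
)
from .training import TrainConfig, train


def _as_float(a):
    if isinstance(a, CountMatrix):
        return a.values.astype(float)
    return np.asarray(a, dtype=float)


def wasserstein2(A, B) -> float:
    """W2 between two empirical distributions (uniform weights).

    Equal sizes: exact optimal assignment.  Unequal sizes: the exact transport
    LP, practical for a few hundred points per side.
    """
    a = _as_float(A)
    b = _as_float(B)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValidationError("A and B must be 2-d with matching dimension")
    cost = cdist(a, b, metric="sqeuclidean")
    n, m = cost.shape
    if n == m:
        rows, cols = linear_sum_assignment(cost)
        return float(np.sqrt(cost[rows, cols].mean()))
    # uniform-weight transport LP
    if n * m > 4_000_000:
        raise ValidationError("unequal-size W2 limited to n*m <= 4e6 points")
    # row constraints then column constraints (drop one redundant row)
    import scipy.sparse as sp

    row_idx = np.repeat(np.arange(n), m)
    col_idx = np.tile(np.arange(m), n)
    data = np.ones(n * m)
    rows_mat = sp.csr_matrix((data, (row_idx, np.arange(n * m))), shape=(n, n * m))
    cols_mat = sp.csr_matrix((data, (col_idx, np.arange(n * m))), shape=(m, n * m))
    A_eq = sp.vstack([rows_mat, cols_mat[:-1]])
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m - 1, 1.0 / m)])
    res = linprog(cost.reshape(-1), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(np.sqrt(res.fun))


def median_heuristic_bandwidth(A, B, max_points: int = 2048) -> float:
    """Median positive pairwise distance of the pooled sample (deterministic
    strided subsample above ``max_points``)."""
    pooled = np.vstack([_as_float(A), _as_float(B)])
    if pooled.shape[0] > max_points:
        stride = int(np.ceil(pooled.shape[0] / max_points))
        pooled = pooled[::stride]
    dists = cdist(pooled, pooled)
    vals = dists[np.triu_indices_from(dists, k=1)]
    pos = vals[vals > 0]
    if pos.size == 0:
        return 1.0
    return float(np.median(pos))


def mmd_rbf2(A, B, bandwidth="median") -> float:
    """Unbiased squared MMD with Gaussian kernel exp(-||a-b||^2 / (2 sigma^2)).

    May be slightly negative by unbiasedness.  bandwidth="median" resolves
    sigma by the median heuristic on the pooled sample.
    """
    a = _as_float(A)
    b = _as_float(B)
    if a.shape[1] != b.shape[1]:
        raise ValidationError("A and B dimensions differ")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need at least 2 points per side (unbiased estimator)")
    if bandwidth == "median":
        sigma = median_heuristic_bandwidth(a, b)
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValidationError("bandwidth must be positive")
    gamma = 1.0 / (2.0 * sigma * sigma)
    kaa = np.exp(-gamma * cdist(a, a, metric="sqeuclidean"))
    kbb = np.exp(-gamma * cdist(b, b, metric="sqeuclidean"))
    kab = np.exp(-gamma * cdist(a, b, metric="sqeuclidean"))
    m, n = a.shape[0], b.shape[0]
    term_a = (kaa.sum() - np.trace(kaa)) / (m * (m - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (n * (n - 1))
    return float(term_a + term_b - 2.0 * kab.mean())


@dataclass(frozen=True)
class MetricReport:
    per_seed: tuple  # of (seed, w2, mmd2)
    failures: tuple = ()

    @property
    def w2_values(self):
        return np.array([r[1] for r in self.per_seed])

    @property
    def mmd2_values(self):
        return np.array([r[2] for r in self.per_seed])

    @property
    def w2_mean(self):
        return float(self.w2_values.mean())

    @property
    def w2_std(self):
        return float(self.w2_values.std(ddof=1)) if len(self.per_seed) > 1 else 0.0

    @property
    def mmd2_mean(self):
        return float(self.mmd2_values.mean())

    @property
    def mmd2_std(self):
        return float(self.mmd2_values.std(ddof=1)) if len(self.per_seed) > 1 else 0.0


def benchmark_simulation(
    train_cfg: TrainConfig | None = None,
    sampler_cfg: SamplerConfig | None = None,
    coupling_kind: str = "independent",
    seeds=(0, 1, 2, 3, 4),
    n_eval: int = 2000,
    n_train: int = 10000,
    target_spec=None,
    source_spec=None,
    arch: ArchConfig | None = None,
    model_factory=None,
) -> MetricReport:
    """Full 2D benchmark: per seed, generate data, train, sample, score.

    model_factory(seed) -> rate model overrides training entirely (used to
    run the analytic-rate oracle through the same harness).
    """
    if not seeds:
        raise ValidationError("seeds must be nonempty")
    target_spec = target_spec or default_mixture_spec()
    source_spec = source_spec or default_source_spec(target_spec.d)
    arch = arch or ArchConfig()
    if train_cfg is None:
        # exact minibatch OT is solved per step; a smaller minibatch keeps the
        # assignment cheap while the plan stays exact
        train_cfg = TrainConfig(batch_size=64) if coupling_kind == "ot" else TrainConfig()
    base_train = train_cfg
    base_sampler = sampler_cfg or SamplerConfig()
    per_seed = []
    failures = []
    for seed in seeds:
        sub = spawn_seeds(int(seed), 6)
        try:
            target_train = sample_gamma_poisson_mixture(target_spec, n_train, sub[0])

            def source_sampler(n, s):
                return sample_uniform_grid(source_spec, n, s)

            if model_factory is not None:
                model = model_factory(seed)
            else:
                model = init_rate_model(target_spec.d, arch, seed=sub[1])
                cfg = dataclasses.replace(
                    base_train, coupling=coupling_kind, seed=sub[2])
                model, _ = train(model, source_sampler, target_train, cfg)
            x_init = sample_uniform_grid(source_spec, n_eval, sub[3])
            scfg = SamplerConfig(K=base_sampler.K, eps=base_sampler.eps,
                                 guidance=base_sampler.guidance, seed=sub[4])
            generated = simulate(model, x_init, config=scfg)
            target_eval = sample_gamma_poisson_mixture(target_spec, n_eval, sub[5])
            w2 = wasserstein2(generated, target_eval)
            mmd2 = mmd_rbf2(generated, target_eval)
            per_seed.append((int(seed), w2, mmd2))
        except Exception as exc:  # noqa: BLE001 - benchmark must report, not die
            warnings.warn(f"benchmark run for seed {seed} failed: {exc}")
            failures.append((int(seed), repr(exc)))
    if not per_seed:
        raise RuntimeError("every benchmark run failed")
    return MetricReport(tuple(per_seed), tuple(failures))


# ---- conditional-generation metrics --------------------------------------

@dataclass(frozen=True)
class ConditionalMetricReport:
    rmse_mu: float
    rmse_var: float
    rmse_zero: float
    cov_f: float
    contrast: float
    per_bin: dict = field(default_factory=dict, compare=False)


def conditional_metrics(real_counts, generated_counts, bin_ids, gen_bin_ids,
                        active_mask=None) -> ConditionalMetricReport:
    """Bin-conditioned fidelity metrics between real and generated counts.

    Means, variances, and zero fractions are compared per covariate bin with
    n_b (real bin occupancy) weights; covariance structure is compared via the
    Frobenius norm of off-diagonal covariance matrices over active coordinates;
    contrast summarizes tuning sharpness of the generated means,
    (max_b - median_b) / mean_b per active coordinate.
    """
    real = _as_float(real_counts)
    gen = _as_float(generated_counts)
    bin_ids = np.asarray(bin_ids)
    gen_bin_ids = np.asarray(gen_bin_ids)
    if real.shape[1] != gen.shape[1]:
        raise ValidationError("real and generated dimensions differ")
    if bin_ids.shape[0] != real.shape[0] or gen_bin_ids.shape[0] != gen.shape[0]:
        raise ValidationError("bin ids must align with their count matrices")
    d = real.shape[1]
    if active_mask is None:
        active_mask = real.sum(axis=0) > 0
    active_mask = np.asarray(active_mask, dtype=bool)

    bins = [b for b in np.unique(bin_ids) if (gen_bin_ids == b).any()]
    if not bins:
        raise ValidationError("no bin is present in both real and generated data")
    per_bin = {}
    n_tot = 0.0
    n_tot_2 = 0.0  # bins usable for variance/covariance
    sq_mu = sq_var = sq_zero = cov_sum = 0.0
    mu_hat_rows = []
    for b in bins:
        r = real[bin_ids == b]
        g = gen[gen_bin_ids == b]
        n_b = r.shape[0]
        mu = r.mean(axis=0)
        mu_hat = g.mean(axis=0)
        zero = (r == 0).mean(axis=0)
        zero_hat = (g == 0).mean(axis=0)
        entry = {"n_b": n_b, "mu": mu, "mu_hat": mu_hat}
        n_tot += n_b
        sq_mu += n_b * ((mu_hat - mu) ** 2).sum()
        sq_zero += n_b * ((zero_hat - zero) ** 2).sum()
        mu_hat_rows.append(mu_hat)
        if r.shape[0] >= 2 and g.shape[0] >= 2:
            var = r.var(axis=0, ddof=1)
            var_hat = g.var(axis=0, ddof=1)
            c = np.cov(r[:, active_mask], rowvar=False)
            c_hat = np.cov(g[:, active_mask], rowvar=False)
            c = np.atleast_2d(c) - np.diag(np.diag(np.atleast_2d(c)))
            c_hat = np.atleast_2d(c_hat) - np.diag(np.diag(np.atleast_2d(c_hat)))
            sq_var += n_b * ((var_hat - var) ** 2).sum()
            cov_sum += n_b * np.linalg.norm(c_hat - c, ord="fro")
            n_tot_2 += n_b
            entry.update({"C": c, "C_hat": c_hat})
        else:
            warnings.warn(f"bin {b!r} has < 2 observations; excluded from "
                          "variance/covariance terms")
        per_bin[b] = entry
    rmse_mu = float(np.sqrt(sq_mu / (n_tot * d)))
    rmse_zero = float(np.sqrt(sq_zero / (n_tot * d)))
    rmse_var = float(np.sqrt(sq_var / (n_tot_2 * d))) if n_tot_2 else float("nan")
    cov_f = float(cov_sum / n_tot_2) if n_tot_2 else float("nan")

    mu_hat_mat = np.vstack(mu_hat_rows)  # bins x d
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast_j = (
            mu_hat_mat.max(axis=0) - np.median(mu_hat_mat, axis=0)
        ) / mu_hat_mat.mean(axis=0)
    contrast = float(np.nanmean(contrast_j[active_mask]))
    return ConditionalMetricReport(rmse_mu, rmse_var, rmse_zero, cov_f, contrast,
                                   per_bin)
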