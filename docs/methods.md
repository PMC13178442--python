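# Methods

## Model

`countfm` models transport between two populations of nonnegative integer
count vectors — a source `x0 ~ p0` and a target `x1 ~ p1` on `N_0^d` — as a
continuous-time Markov jump process whose only transitions are unit births and
deaths in single coordinates. Over a short interval `h`, coordinate `i` gains
a count with probability `h * birth_i(x, t)` and loses one with probability
`h * death_i(x, t)`; death at `x_i = 0` is disallowed. Because every
transition is a local unit jump, intermediate states are themselves count
vectors, and the output dimension of the learned rate field is `2d` regardless
of the count range — the structural advantage over categorical-state
formulations whose output grows with the maximum count.

## Conditional binomial bridge

Given an endpoint pair, the conditional path is defined coordinatewise:

    X_t(i) = x0(i) + sgn(x1(i) - x0(i)) * B_t(i),
    B_t(i) ~ Binomial(|x1(i) - x0(i)|, t),

independently across coordinates given (x0, x1). Its mean moves linearly from
x0 to x1 and both endpoints are pinned. Substituting the (reflected) binomial
marginal into the one-dimensional Kolmogorov forward equation gives the
closed-form conditional rates

    birth_i(x | x0, x1) = (x1(i) - x(i))_+ / (1 - t),
    death_i(x | x0, x1) = (x(i) - x1(i))_+ / (1 - t),

with `1 - t` regularized to `1 - t + eps_t`. The forward-equation residual is
verified numerically in the test suite by central finite differences of the
exact binomial pmf (residuals below 1e-6 on a grid of endpoints up to 20 and
times 0.1-0.9).

## Training objective

The model is a single MLP with shared hidden layers and separate output heads
for `d` birth rates and `d` death *coefficients*; death rates are
`mu = x * beta(x, t)` so that the zero boundary is safe for any parameters.
Both heads pass through a softplus (an exponential map was rejected for
stability). Training minimizes the generalized-KL score

    l(u, v) = v - u * log(v + eps_l)

between the analytic conditional rates u and the model rates v, summed over
coordinates and heads, with single-sample estimation: one
`t ~ Uniform[eps_t, 1 - eps_t]` and one bridge draw per endpoint pair per
step. `l(u, .)` is a proper score minimized at `v = u`, so fitting the
conditional rates fits the marginal rates of the mixture-of-bridges path.

## Endpoint coupling

Three couplings are implemented: independent (product of the empirical
marginals), exact minibatch OT under the symmetric Poisson cost
`c(x, y) = sum_i x_i log((x_i+eps_c)/(y_i+eps_c)) + y_i log((y_i+eps_c)/(x_i+eps_c))`,
and group-restricted OT (exact OT within label-compatible source/target
groups only). Because the minibatch problem has uniform marginals on
equal-size supports, a permutation optimum always exists; the plan is
computed exactly with the Jonker-Volgenant assignment solver rather than an
entropic approximation. Endpoint pairs are drawn from the plan with
replacement by default; deterministic extraction of the optimal permutation
is available (`ot_sample_pairs=False`). Unequal group sizes in restricted OT
are equalized by seeded subsampling of the larger side.

## Sampling

Generation integrates the learned process from `t = eps_t` to `1 - eps_t`
with a first-order local-jump scheme: with `K` steps of size
`Delta = (1 - 2 eps_t)/K` and total rate `r_i = birth_i + death_i`,

    p_stay  = exp(-r_i Delta)
    p_birth = (1 - exp(-r_i Delta)) birth_i / (r_i + eps_r)
    p_death = (1 - exp(-r_i Delta)) death_i / (r_i + eps_r)

one of {stay, +1, -1} is sampled per coordinate and all coordinates are
updated simultaneously (sequential within-step updates would be
order-dependent). Rates are evaluated at the left endpoint of each step.
Classifier-free guidance combines conditional and unconditional rates as
`uncond + w (cond - uncond)`, clamped at zero; `w = 0` and `w = 1` reproduce
the unconditional and conditional models exactly, and intermediate values cost
two rate evaluations per step (NFE = 2K).

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `eps_t` | 1e-4 | regularizes `1/(1-t)`; bounds trainer/sampler times to `[eps_t, 1-eps_t]`. Under the regularized rate a pending unit survives the whole window with probability `2*eps_t`, so the expected number of unpinned units per trajectory is `2*eps_t*sum|x1-x0|`; 1e-4 keeps that below 0.01 for gaps of tens of counts while the analytic targets stay bounded. |
| `eps_l` | 1e-6 | keeps the loss finite when the model emits a zero rate for a positive target. |
| `eps_r` | 1e-8 | guards the division by `r_i` in the sampler when all rates vanish; the induced normalization slack is at most `(1-e^{-r Delta}) eps_r/(r+eps_r)`. |
| `eps_c` | 1e-3 | stabilizes the Poisson transport cost at zero counts. |
| hidden widths | (32, 32) | small time-varying MLP, SELU activations; adequate for low-dimensional count targets. Larger backbones plug into `ArchConfig`. |
| time embedding | `t` plus 4 sine/cosine pairs at dyadic frequencies | gives the MLP resolution in `t` without recurrence. |
| input scaling | raw counts (`log1p=False`) | raw counts trained measurably better than log1p in the two-dimensional benchmark regime; `log1p=True` is recommended for high-count, high-dimensional data. |
| optimizer | Adam, lr 1e-3, global-norm clip 10 | the analytic targets can spike near `t = 1` (`~gap/(2 eps_t)`); clipping absorbs these rare large-gradient steps. A cosine lr schedule is available (`lr_schedule="cosine"`). |
| weight averaging | EMA, decay 0.999 (warmup-capped at `(1+t)/(10+t)`) | the constant-lr final iterate is a noisy sample around the optimum and occasionally lands badly; averaging the last ~1000 steps removes this seed-to-seed variance. Set `ema_decay=0` to disable. |
| training | 40,000 steps, batch 256 (independent) / 64 (OT) | the benchmark protocol below; the smaller OT minibatch keeps the per-step exact assignment cheap while the plan remains exact. |
| sampler | K = 500 | endpoint-pinning error decays roughly like `exp(-(ln K + gamma))` per pending unit under the left-endpoint scheme; K = 500 pins >= 99% of small-gap trajectories and is where benchmark quality plateaus. |
| `condition_dropout_prob` | 0.1 | fraction of training rows whose covariate embedding is replaced by the learned null embedding. |

## Synthetic benchmark

The built-in benchmark target is an equal-weight mixture of two Gamma-Poisson
components in two dimensions with componentwise modes (60, 5) and (60, 40);
the source is a discrete uniform on the grid {0..79} x {0..59}, which covers
the target's data range with margin. Only the modes pin the mixture down, so
the gamma shape defaults to r = 50 per coordinate with scale `mode/(r-1)`,
which places the gamma mode (and, closely, the negative-binomial mode) at the
requested location with realistic overdispersion. Each benchmark run draws
10,000 training target samples, trains from scratch, simulates 2,000 samples
from fresh source draws, and scores W2 (exact assignment, Euclidean ground
metric, raw counts) and unbiased squared MMD (Gaussian RBF, median-heuristic
bandwidth on a deterministic strided subsample of the pooled points) against
a fresh 2,000-sample target draw, repeated over 5 seeds.

What the generator does not emulate: real scRNA-seq sparsity patterns,
library-size variation, gene-gene correlation beyond the two-component
structure, or any temporal structure in spike trains. Passing the benchmark
shows the bridge/loss/sampler machinery transports between genuinely
overdispersed count distributions; it says nothing about scaling to thousands
of coordinates, which needs a larger backbone (supported via `ArchConfig` but
not benchmarked here).

## Numerical and design notes

- Equal endpoint coordinates consume no randomness in the bridge sampler, so
  equal and unequal endpoints stay on the same RNG stream.
- All randomness derives from integer seeds; child streams are split with
  `numpy.random.SeedSequence`.
- The sampler zeroes death probabilities at `x = 0` defensively even for
  user-supplied rate objects that are not boundary-safe.
- Guided rates with `w > 1` can extrapolate below zero; they are clamped at 0
  and the occurrences counted in a debug log.
- W2 between unequal-size clouds is solved as the exact transport LP
  (practical to a few hundred points per side); the benchmark always compares
  equal-size clouds via assignment.
- The neural network and Adam are implemented directly on numpy arrays; at
  these widths the computation is a handful of small matrix products per step
  and a tensor framework adds nothing.
- Conditional-metric bins with fewer than two observations are excluded from
  variance/covariance terms with a warning; "active" coordinates default to
  those with nonzero total count in the real data.

## Known limitations

- The binomial bridge is deliberately simple; more stochastic bridges
  (beta-binomial, latent interpolants) are out of scope.
- The first-order left-endpoint sampler truncates the rate singularity near
  `t = 1`; per-unit pinning error decays like `1/K` up to log factors, so very
  large endpoint gaps need proportionally more steps.
- Only minibatch OT is implemented, not population-level OT; the coupling a
  minibatch plan induces is an empirical approximation.
- The benchmark's Table-style numbers depend mildly on the unspecified gamma
  shape, grid extent, evaluation size, and MMD bandwidth; defaults are fixed
  once (above) and used everywhere.
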