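# countfm — flow matching for count data

`countfm` is a generative-modeling library for vectors of nonnegative integer
counts — single-cell RNA-seq expression profiles, neural spike counts,
ecological abundances. Continuous flow matching and diffusion models need an
embedding or dequantization step to handle such data, and discrete diffusions
over categorical state spaces need an output dimension that grows with the
maximum count. `countfm` instead learns a continuous-time Markov **birth–death
process directly on the count lattice**: every intermediate state is a valid
count vector, and the learned rate field has output dimension `2d` no matter
how large the counts get.

## The model in brief

Given a source distribution `p0` and a target `p1` on `N_0^d`, the generative
process is a CTMC whose only transitions are unit jumps `x -> x ± e_i`
(death is disallowed at `x_i = 0`). Training is simulation-free:

1. **Conditional bridge.** For an endpoint pair `(x0, x1)`, each coordinate
   interpolates by a time-rescaled binomial,
   `X_t(i) = x0(i) + sgn(x1(i) − x0(i)) · Binomial(|x1(i) − x0(i)|, t)`,
   which pins both endpoints. Its Kolmogorov forward equation is solved in
   closed form by the rates
   `birth_i = (x1(i) − x(i))_+ / (1 − t)`, `death_i = (x(i) − x1(i))_+ / (1 − t)`.
2. **Regression.** A small MLP `(x, t) -> (birth, death)` is fit to these
   analytic conditional rates under the generalized-KL score
   `l(u, v) = v − u log(v + eps)`, a proper scoring rule minimized at `v = u`;
   minimizing it over random endpoint pairs, times, and bridge states recovers
   the marginal rates of the mixture of bridges. Death rates are parameterized
   as `x ⊙ beta(x, t)` so the zero boundary is safe by construction.
3. **Sampling.** New samples integrate the learned process from a source draw
   with `K` first-order steps: per coordinate, stay/birth/death probabilities
   `exp(−rΔ)`, `(1 − exp(−rΔ)) · birth/r`, `(1 − exp(−rΔ)) · death/r`.

Endpoint pairs can be coupled independently, by **exact minibatch optimal
transport** under a symmetric Poisson cost (solved as an assignment problem),
or by group-restricted OT when pairings must respect known labels (e.g.
lineage constraints). Covariate conditioning with classifier-free guidance is
supported throughout.

See [docs/methods.md](docs/methods.md) for the full scientific account,
parameter defaults, and limitations.

## Worked example

Train a model to transport a uniform grid onto a bimodal Gamma-Poisson
mixture (the built-in 2D benchmark distributions), then generate and score
samples:

```python
import countfm as cf

# target: equal-weight 2D Gamma-Poisson mixture with modes (60, 5) and (60, 40)
target = cf.sample_gamma_poisson_mixture(cf.default_mixture_spec(), 4000, seed=0)
# source: discrete uniform on {0..79} x {0..59}
source = cf.sample_uniform_grid(cf.default_source_spec(), 4000, seed=1)

model = cf.init_rate_model(d=2, seed=2)
model, history = cf.train(model, source, target,
                          cf.TrainConfig(steps=12000, batch_size=256, seed=3))
print(f"loss: {history[0].total:.3f} (first) -> {history[-1].total:.3f} (last)")

x0 = cf.sample_uniform_grid(cf.default_source_spec(), 1000, seed=4)
gen = cf.simulate(model, x0.values, config=cf.SamplerConfig(K=500, seed=5))
ref = cf.sample_gamma_poisson_mixture(cf.default_mixture_spec(), 1000, seed=6)

print(f"generated mean: {gen.values.mean(axis=0).round(1)}   "
      f"target mean: {ref.values.mean(axis=0).round(1)}")
print(f"W2(generated, target)  = {cf.wasserstein2(gen.values, ref.values):.3f}")
print(f"W2(source, target)     = {cf.wasserstein2(x0.values, ref.values):.3f}")
```

Output (about 25 seconds on one CPU core):

```
loss: 94.995 (first) -> -94.885 (last)
generated mean: [60.3 24.4]   target mean: [61.2 22.9]
W2(generated, target)  = 3.741
W2(source, target)     = 27.549
```

This short run already moves the transport most of the way; the full
benchmark protocol (40,000 steps, 10,000 training draws, 2,000-sample
evaluation) reaches mean W2 ≈ 2.5 over five seeds, against a floor of ≈ 1.8
measured between two independent 2,000-point draws of the target itself.

The same pipeline is available from the command line:

```bash
countfm simulate --kind mixture --n 4000 --seed 0 --out target.csv
countfm simulate --kind grid    --n 4000 --seed 1 --out source.csv
printf 'steps: 12000\n' > train.yaml
countfm train --source source.csv --target target.csv --config train.yaml \
    --seed 3 --out model.npz
countfm sample --ckpt model.npz --n 1000 --steps 500 --seed 5 --out generated.csv
countfm evaluate --real target.csv --generated generated.csv --out metrics.json
```

## Repository layout

```
src/countfm/
  synthetic.py    Gamma-Poisson mixture / uniform-grid generators, fixtures
  bridge.py       binomial bridge, closed-form conditional rates, residual oracle
  rate_model.py   numpy MLP rate field, guidance, checkpointing
  coupling.py     independent / exact-OT / group-restricted endpoint couplings
  training.py     generalized-KL objective, Adam loop
  sampler.py      first-order local-jump CTMC sampler
  evaluation.py   W2, MMD, conditional fidelity metrics, benchmark harness
  io.py, cli.py   CSV/MTX readers and the `countfm` command-line interface
docs/methods.md   scientific documentation
tests/            unit, property, and end-to-end benchmark tests
```
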