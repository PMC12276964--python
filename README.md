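# mapnn

Estimation of spatially heterogeneous maps of **population density** and
**dispersal rate** from geo-referenced SNP genotypes, using a neural
network trained on simulated data.

## The problem

Local population density D (individuals per unit area) and the effective
dispersal rate σ (the root-mean-square distance along one spatial axis
between an offspring and a random parent, per generation) vary across
real landscapes, and both shape spatial genetic variation.  Existing
genetic methods either estimate a single population-wide value, require
identity-by-descent blocks, or return only *relative* effective-migration
surfaces.  This package infers the *magnitudes* of both parameters and
their variation over space from data most non-model systems can supply:
a few thousand biallelic SNPs with sampling coordinates for ~100
individuals.

## The approach

Training data are simulated: random demographic maps (a `w x w` grid of
σ and carrying-capacity K values, built from 1–3 polynomial-bounded
segments with log-uniform priors) drive a continuous-space,
individual-based simulator (Gaussian mate choice and natal dispersal,
competition-based mortality with survival `1/(1 + c·η/K)`).  Recorded
ancestry is completed backward in time by a randomly mating coalescent
("recapitation"), and mutations are overlaid with a rate-doubling
schedule that yields an exact SNP count.  The network has two branches:
a shared 1-D convolutional encoder producing 128 learned summaries per
*pair* of individuals (matrix G), and a dense branch scoring the spatial
relevance of every pair to every grid cell (non-negative scores S_i).
Per cell i,

    y_i = f( Σ_j ReLU( (G ⊙ S_i) W + b )_j ),

summing over pairs j, with f a small dense stack whose two outputs are
the cell's dispersal and density values — a `w x w x 2` map.  Training
minimizes the mean squared error over grid cells of log-transformed,
per-channel standardized target maps.  Point estimates average many
forward passes over random pair subsets; uncertainty comes from a
parametric bootstrap (simulate under the estimated map, re-estimate,
take per-cell quantiles).

See `docs/methods.md` for the full model description, parameter
defaults, and limitations.

## Worked example

A complete miniature run — simulate training data, train a reduced
network, predict and score a held-out map — from the command line:

```bash
mapnn end-to-end --set out=demo --set seed=5 --set width=8 \
  --set n_sims=3 --set draws_per_sim=2 --set sampling.n=10 \
  --set genotypes.m_target=60 --set sim.n_cycles=60 --set sim.burn_in=20 \
  --set train.max_epochs=2 --set pairs.k_init=20 --set pairs.k_extract=10 \
  --set ensemble=2 --set model.n_features=8 --set model.loc_hidden=8 \
  --set model.combiner_hidden=8 --set model.f_hidden=8 \
  --set model.conv_channels=[8] --set model.pool=4
```

prints (numbers from this exact command; the model is deliberately tiny,
so the errors are large):

```json
{
 "mrae_dispersal": 0.24035156081352183,
 "mrae_density": 0.36351961100887153,
 "r2_dispersal": NaN,
 "r2_density": 0.4696301300843928,
 "n_cells_evaluated": 64
}
```

`mrae_dispersal` is the mean over grid cells of |estimate − truth|/truth
for the dispersal channel (0.24 = 24% average relative error);
`r2_dispersal` is `NaN` here because the held-out true dispersal map is
flat (zero variance, so a correlation is undefined).  The run directory
`demo/` holds the estimated map grids (`estimate_*.csv`), the training
history, a reloadable checkpoint, and `run.json` with the resolved
configuration and seed.  Other subcommands (`generate-maps`, `simulate`,
`sample`, `genotypes`, `train`, `predict`, `evaluate`, `bootstrap`)
expose the individual pipeline stages; `--help` lists them.

In library form the same pipeline is three calls:

```python
import numpy as np
from mapnn.pipeline import random_map, simulate_source, dataset_from_source
from mapnn.simulate import SimParams

rng = np.random.default_rng(1)
dmap = random_map((0.73, 3.08), (4, 12), rng, width=25)     # σ and K priors
src = simulate_source(dmap, SimParams(n_cycles=750, burn_in=250), rng)
ds = dataset_from_source(src, n=20, m_target=250, rng=rng)  # genotypes + coords
```

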