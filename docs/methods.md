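# Methods

This package estimates spatially heterogeneous maps of population
density and dispersal rate from geo-referenced SNP genotypes, by
training a neural network on simulated data.  This note documents the
models and procedures it implements, the choices made where the design
was genuinely open, and what the bundled studies do and do not show.

## Demographic maps

A demographic map is a `w x w x 2` grid: channel 0 holds the effective
dispersal rate sigma (distance units per generation), channel 1 the
carrying capacity K (individuals per unit area).  Random maps are built
from one polynomial boundary curve whose degree is uniform on
{0, 1, 2, 3}; degree 0 yields a flat map with a single log-uniform value
from the channel's prior `(p_min, p_max)`.  Otherwise the curve is the
interpolating polynomial through `degree + 1` points uniform on the
habitat square, each grid cell is classified below/above the curve at
its center `(i + 0.5, j + 0.5)`, and 4-connected components of that
binary field become segments.  A single curve can produce more than two
components (e.g. a cubic that exits through the bottom edge); components
beyond the configured maximum (3 by default) are merged into the kept
component with the nearest centroid.  Segment values: the map's value
range `r` is uniform on `(p_min, p_max)` (redrawn until it fits inside
the prior width, which keeps the subsequent draw feasible), the map
minimum `v_min` is log-uniform on `(p_min, p_max - r)`, two segments get
`{v_min, v_min + r}` and further segments get uniform values strictly
inside.  Finally one of the eight flips/rotations of the square is
applied to each channel independently of the other.

For irregular habitats a boolean mask zeroes both channels outside the
range; masked cells are excluded from the loss and all metrics.  A
viability correction for harsh parameter combinations fits
`log(sigma_min) = m log K + b` by bisection on a stability predicate
over a pilot grid of K values, and raises one randomly chosen channel of
each offending cell to the threshold times a 1.25 boost (a
`1 + Uniform(0, 0.25)` variant is available).

## Forward simulator

The simulator is individual-based in continuous space with overlapping
generations.  Each cycle: (1) every individual draws a mate from its
neighbors within `3 sigma_m`, weighted by a Gaussian density with SD
`sigma_m`, and produces `Poisson(1/L)` offspring (`L = 4` is the rough
mean lifetime at stationarity); (2) offspring land at the mother's
location plus a per-axis Gaussian displacement with SD `sigma_f`;
proposals outside the habitat (or mask) are discarded without retry;
(3) mortality applies to everyone, newborns included: individual i
survives with probability `p_i = 1 / (1 + c * eta_i / K_i)`, where
`eta_i` is the sum of Gaussian competition kernels (SD `sigma_c`,
truncated at 3 SD, normalized by `1/(2 pi sigma_c^2)` so that `eta`
approximates local density) and `K_i` is the carrying capacity
bilinearly interpolated at i's location.  Adults are sessile between
cycles.  Map parameters for an individual are bilinear interpolations of
the four surrounding cell-center values, clamped at edges.

The estimand sigma is the RMS distance along one axis from an offspring
to a uniformly chosen parent.  Composing the two dispersal sources gives
`sigma^2 = sigma_f^2 + sigma_m^2 / 2` (the father adds the mate distance
with probability 1/2), so the simulator derives `sigma_f` from the map's
sigma value at the mother's location; map sigma values must therefore
stay above `sigma_m / sqrt(2)`.

The survival constant `c` is exposed in `SimParams.competition_scale`.
Its default, 0.225, was calibrated with pilot flat-map runs so that the
stationary census density sits near `K / 1.14`, the relation the
realized-vs-input comparison is expected to reproduce; the mean-field
prediction `D/K = 1 / (c q (L + 1))` with `q = 0.9889` (the 3-SD kernel
mass) puts c in the same place.  With the calibrated default,
heterogeneous benchmark-style runs show input K exceeding realized
density by ~14-18% and input sigma sitting within a few percent of
realized sigma (slightly *below* zero offset: the 3-SD truncation of the
mating kernel and the discarding of out-of-habitat offspring shave the
realized RMS displacement; flux between segments pushes the other way).

Realized maps are tracked on the same grid as the input map for cycles
after the burn-in (250 by default): density is the time-averaged census
count per unit cell area; realized dispersal pools, per natal cell, both
axis components of the offspring-to-mother and offspring-to-father
displacement vectors (equal weight) into an RMS.  Cells with no
recorded births are flagged missing and excluded from error metrics
rather than imputed.

Extinction: because mortality is competition-based, a lone individual
(`eta = 0`) never dies, so a census of exactly zero is unreachable.  The
simulator declares extinction when the census drops below two — from
there no mating pair can ever form again.

Ancestry is recorded as parentage plus per-transmission recombination
breakpoints (Poisson with the per-bp rate over the genome length;
uniform positions; alternating parental haplotypes from a fair-coin
start).  Multi-chromosome genomes are supported as independent segments
with per-segment rates; segment boundaries recombine with probability
1/2 in the forward pass and are approximated with a log(2)-rate 1-bp
boundary in the backward (coalescent) pass, the standard device for
approximately unlinked chromosomes.

## Genotype synthesis

The recorded forward ancestry is exported to succinct tree-sequence
tables (2 nodes per diploid; node time = cycles before the end of the
run).  Lineages uncoalesced at the start of the forward period are
completed with a randomly mating coalescent whose population size
defaults to the final-cycle census (multi-epoch histories are
configurable), so recent generations are spatially explicit while older
generations approximate random mating.

Rather than fixing a mutation rate, the overlay targets an exact SNP
count m: mutations are added under an infinite-sites model starting at
rate 1e-15 and doubling until at least m sites segregate in the sample,
then exactly m sites are retained as a uniform subsample of all sites
present at the final round.  Fixing m keeps tensors rectangular and
removes the segregating-site count as an information channel, and in
empirical use lets training data match a focal dataset.  Genotypes are
recoded per column to minor-allele counts; at an exact 50/50 frequency
the allele with the lexicographically first label ("0", the ancestral
state) is counted, which makes the coding deterministic.  VCF output
discretizes the continuous infinite-sites positions to distinct integer
coordinates (collisions redrawn); the reader drops non-biallelic
records, indels, and sites with missing calls, and reports the counts.

## Sampling strategies

Three schemes choose whose genotypes enter a dataset: uniform without
replacement over living individuals; a `g x g` grid with a fixed quota
per cell (errors on deficient cells rather than silently under-sampling);
and "fixed" target coordinates for mirroring an empirical design — each
target claims a random not-yet-taken individual within a radius starting
at 2% of the map width and doubling until someone is found (a switch
selects the nearest candidate instead).

## Network

The model has two branches.  Branch 1 is a pairwise convolutional
encoder: for each sampled pair of individuals, the two genotype columns
form an `m x 2` array (phased mode: `m x 4`) processed by shared-weight
blocks of 1-D convolution (kernel 7, ReLU) and average pooling (width
10), repeated until the sequence length is at most 64, then flattened
through a dense layer into F = 128 features per pair (row j of the
matrix G).  Branch 2 turns a table with one row per (grid cell, pair) —
cell center, both individuals' coordinates, and the map width, with
coordinates pre-divided by the width — through two dense+ReLU layers
into F non-negative spatial scores per (cell, pair), the slice S_i for
cell i.  The combiner computes per cell

    y_i = f( sum_j ReLU( (G . S_i) W + b )_j )

with elementwise product, a trainable `F x H` map (H = 128), and f a
dense(128)+ReLU+dense(2) stack whose two outputs are the cell's
dispersal and density values; the `w^2 x 2` result is reshaped to
`w x w x 2`.  Parameter count is independent of the pair count and the
map width.  The batched implementation is tested against the literal
per-cell/per-pair loop.

Large samples are handled by analysing a random subset of `k_init`
pairs, of which only `k_extract` propagate gradients into the encoder
(a stop-gradient on the other rows of G); the locations branch and
combiner always see all `k_init` pairs.  Pairs are order-normalized
(smaller index first).

Two numerical choices depart from a literal transcription of the
combiner.  The pair sum is divided by the pair count (a constant
absorbable into the output stack's first layer; without it activations
scale with `k_init` and optimization conditions poorly).  And an
optional "relatedness" pair encoding appends two derived input
channels — the per-site absolute difference and product of the two
allele counts — which makes identity-by-state style summaries linearly
readable by the first convolution; this matters in small-data regimes
where the encoder would otherwise need many examples to synthesize the
product terms itself.

No deep-learning framework is used: the package carries a compact numpy
layer engine (dense, 1-D convolution, average pooling, ReLU, Adam) with
hand-written backward passes, gradient-checked against finite
differences in the test suite.  Float32 mode roughly halves CPU
training time and is used by the bundled studies; float64 is the
default elsewhere.

## Training

Targets are the simulation-input maps (realized maps are reserved for
evaluation).  Targets are log-transformed and each channel centered and
scaled with statistics from the training split only.  The loss is the
mean squared error over both channels of all grid cells (denominator
`2 w^2`), restricted to habitable cells when a mask is present
(denominator twice the habitable-cell count).  Optimization uses Adam
(learning rate 1e-4, batch 10, 20% validation split by default);
weights start Glorot-uniform, biases zero.  The learning rate halves
after every 10 consecutive epochs without a strict validation
improvement and training stops after 100 such epochs (both exposed;
`min_delta` defaults to 0), restoring the best-validation weights.
Simulations are reusable: several sample sets can be drawn per
simulation with replacement, each becoming a dataset that shares the
target map.

## Prediction, metrics, uncertainty

A point estimate averages R back-transformed forward passes made with
independent random pair subsets (R = 100 at full scale).  Accuracy per
channel is the mean relative absolute error, MRAE = mean over evaluated
cells of |estimate - truth| / truth; cells excluded by the mask or with
missing realized values are skipped.  The squared Pearson correlation
between estimated and true cell values (natural scale; log option) is
reported alongside.  Uncertainty comes from a parametric bootstrap:
B datasets are simulated under the estimated map, each re-estimated,
and per-cell empirical 2.5%/97.5% quantiles (linear interpolation
between order statistics) form a 95% band, also reported relative to
the point estimate.  Replicates whose simulation goes extinct are
redrawn with fresh seeds and counted.

## Bundled studies and their scales

Two study routines back the package's own validation; both run on one
CPU.

*Simulator calibration* (`benchmark.calibration_study`): 10 seeded
heterogeneous-map simulations at w=25 with the benchmark priors
(sigma log-uniform on (0.73, 3.08), K on (4, 12), sigma_m = sigma_c = 1),
750 cycles with a 250-cycle burn-in.  It reports the mean percent by
which input sigma falls below realized sigma and input K exceeds
realized density, averaged over habitable cells and replicates.  The
reduced width and cycle count (the full benchmark uses a 50-cell
habitat and 10,000 cycles) leave the stationary input-vs-realized
relations essentially unchanged, which is what the study measures.

*Parameter recovery* (`benchmark.recovery_study`): an end-to-end check
that training extracts genuine signal.  Fifty simulations (w=10, 1-2
map segments, 250 cycles) each yield six resampled datasets of n=20
individuals and 250 SNPs; a reduced network (F=32, one conv block,
H=32, float32, 80/40 pairs, relatedness pair encoding) trains for up to
30 epochs at learning rate 3e-3, and MRAE on eight held-out simulations
is compared with the no-information baseline that predicts the per-cell
mean of the training targets.  The reduced habitat preserves the
*relative* spatial scale of the full benchmark: dispersal priors and
kernels shrink with the map (sigma on (0.25, 1.0),
sigma_m = sigma_c = 0.3), keeping sigma/w in roughly the benchmark's
range, while the density prior keeps the benchmark's full (4, 40)
span.  Keeping the absolute kernel sizes on a 5x smaller map instead
makes most maps nearly panmictic and leaves little spatial signal for
any method — a property of the scale-down, not of the estimator.  The
same study also checks out-of-range robustness: estimates for data
generated beyond the training priors should stay mostly within a
modest margin of the prior range.

Scale matters for what this study can show.  A full-scale analysis of
this kind trains on tens of thousands of simulated datasets of ~100
individuals and thousands of SNPs; at the desk scale above (300
datasets from 50 simulations, a fifth of the individuals, a twentieth
of the SNPs) the extractable signal per dataset and the sample
efficiency of from-scratch training both bind, and the improvement over
the baseline is accordingly much smaller than a full-scale run would
give.  Dispersal suffers most: its prior spans only ~4x, so the
no-information baseline is already fairly tight.  The study's value is
end-to-end: it demonstrates that the whole pipeline learns genuine
spatial-genetic signal, not that it attains full-scale accuracy.

What these studies show: that the simulator's emergent demography
matches its inputs in the documented way, and that the full pipeline —
simulate, sample, recapitate, overlay, train, predict — extracts real
spatial-genetic signal at desk scale.  What they do not show: accuracy
at full analysis scale (tens of thousands of training simulations,
n=100, thousands of SNPs, GPU training), behaviour on real genotype
data (sequencing error, missingness, LD pruning), or robustness to
demographic histories outside the simulated family.

## Known limitations

- The synthetic data assume neutral sites, no selfing avoidance beyond
  distinct mates, hermaphroditism, sessile adults, and a single
  panmictic epoch beyond the forward window unless configured otherwise.
- The exact layer dimensions of the genotype encoder are package
  defaults honouring the stated constraints (128 features, two dense
  score layers, ReLU non-negativity); they are exposed in `ModelConfig`.
- Density estimation is intrinsically harder than dispersal at small
  sample sizes: it enters through the ratio of neighborhood size to
  sigma^2 and needs many pairs to pin down.
- Bootstrap bands quantify sampling + process noise under the fitted
  map, not model misspecification.
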