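"""Two-branch pairwise network estimating a w x w x 2 demographic map.

Branch 1 runs a shared 1-D convolutional encoder over the genotype
columns of every sampled pair of individuals, producing a feature matrix
G with one row of learned genotype summaries per pair.  Branch 2 turns a
redundant table of (grid-cell center, pair coordinates, map width) rows
into non-negative spatial scores S_i relating every pair to every grid
cell.  The combiner computes, for each cell i,

    y_i = f( sum_j ReLU( (G (.) S_i) W + b )_j )

where (.) is element-wise multiplication, the sum runs over pairs j, and
f is a small stack of dense layers whose two outputs become the
dispersal and density channels of cell i.  Parameter count is
independent of the number of pairs and of the map width.

A random subset of k_init pairs enters the forward pass; gradients reach
the genotype encoder only through k_extract of them (the rest are
stop-gradients in branch 1), which caps the memory of the most expensive
branch without discarding information downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, AvgPool1D, Conv1D, Dense, Param, relu

__all__ = [
    "PairSubsetConfig",
    "ModelConfig",
    "MapNN",
    "enumerate_pairs",
    "all_pairs",
    "build_locations_table",
    "pair_input",
]


@dataclass(frozen=True)
class PairSubsetConfig:
    """How many pairs enter the forward pass / receive encoder gradients."""

    k_init: int
    k_extract: int

    def __post_init__(self):
        if not (1 <= self.k_extract <= self.k_init):
            raise ValueError("require 1 <= k_extract <= k_init")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults: 128 genotype features per pair, two dense score layers with
    ReLU, uniform weight initialization with zero biases, and fixed
    conv/pool dimensions chosen for SNP counts in the thousands."""

    n: int                      # individuals per dataset
    m: int                      # SNP columns
    w: int                      # map width (cells per side)
    n_features: int = 128       # F: genotype summaries per pair
    conv_kernel: int = 7
    conv_channels: tuple = (32, 64)   # first block, then subsequent blocks
    pool: int = 10
    max_conv_len: int = 64      # add conv+pool blocks until length <= this
    loc_hidden: int = 128
    combiner_hidden: int = 128  # H: width of the pair-combination layer
    f_hidden: int = 128         # hidden width of the output stack f
    phased: bool = False
    # "raw": the two individuals' allele counts as 2 channels; "relatedness"
    # additionally exposes per-site |difference| and product, the site-wise
    # ingredients of IBS/relatedness summaries — linearizing what the conv
    # stack would otherwise have to synthesize from few training examples.
    pair_encoding: str = "raw"
    dtype: str = "float64"      # float32 roughly halves CPU training time
    # Normalize the pair sum by the pair count.  This is a reparameterization
    # (the constant is absorbable into the output stack) that keeps activation
    # scales invariant to k_init; without it the summed ReLU terms grow with
    # the number of pairs and optimization conditions poorly.
    normalize_pairs: bool = True

    @property
    def pair_channels(self) -> int:
        base = 4 if self.phased else 2
        return base + (2 if self.pair_encoding == "relatedness" else 0)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type


def all_pairs(n: int) -> np.ndarray:
    """All unordered pairs (a < b) of n individuals, lexicographic order."""
    a, b = np.triu_indices(n, k=1)
    return np.stack([a, b], axis=1)


def enumerate_pairs(n: int, config: PairSubsetConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample k_init pairs without replacement; flag k_extract gradient-active.

    Returns (pairs (k_init, 2), extract_mask (k_init,) bool).  Pairs are
    order-normalized (smaller individual index first).
    """
    pool = all_pairs(n)
    total = pool.shape[0]
    if config.k_init > total:
        raise ValueError(f"k_init={config.k_init} exceeds {total} available pairs")
    pairs = pool[rng.choice(total, size=config.k_init, replace=False)]
    mask = np.zeros(config.k_init, dtype=bool)
    mask[rng.choice(config.k_init, size=config.k_extract, replace=False)] = True
    return pairs, mask


def pair_input(genotypes: np.ndarray, pairs: np.ndarray, phased: bool = False,
               encoding: str = "raw") -> np.ndarray:
    """Stack the two individuals' genotype columns: (k, m, channels).

    With ``encoding="relatedness"`` two derived channels are appended:
    the per-site absolute difference and product of the allele counts.
    """
    if phased:
        cols = [np.stack([genotypes[2 * a], genotypes[2 * a + 1],
                          genotypes[2 * b], genotypes[2 * b + 1]], axis=-1)
                for a, b in pairs]
    else:
        cols = [np.stack([genotypes[a], genotypes[b]], axis=-1) for a, b in pairs]
    out = np.asarray(cols, dtype=float)
    if encoding == "relatedness":
        ga = out[..., : out.shape[-1] // 2].sum(axis=-1)
        gb = out[..., out.shape[-1] // 2:].sum(axis=-1)
        out = np.concatenate([out, np.abs(ga - gb)[..., None], (ga * gb)[..., None]],
                             axis=-1)
    elif encoding != "raw":
        raise ValueError(f"unknown pair encoding {encoding!r}")
    return out


def build_locations_table(sample_locations: np.ndarray, pairs: np.ndarray,
                          w: int) -> np.ndarray:
    """One row per (grid cell, pair): 7 columns, cell-major then pair.

    Columns: cell center x, y; the two individuals' coordinates; the map
    width.  Coordinates are divided by w (the width column stays raw), a
    deliberately redundant but optimization-friendly encoding.
    """
    k = pairs.shape[0]
    iy, ix = np.divmod(np.arange(w * w), w)
    centers = np.stack([ix + 0.5, iy + 0.5], axis=1)  # cell i = iy*w + ix
    rows = np.empty((w * w, k, 7))
    rows[:, :, 0:2] = centers[:, None, :] / w
    rows[:, :, 2:4] = sample_locations[pairs[:, 0]][None, :, :] / w
    rows[:, :, 4:6] = sample_locations[pairs[:, 1]][None, :, :] / w
    rows[:, :, 6] = w
    return rows.reshape(w * w * k, 7)


class MapNN:
    """The two-branch network with hand-rolled forward/backward passes."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        dt = c.np_dtype
        # --- branch 1: shared pairwise genotype encoder
        self.conv_stack: list = []
        length, ch = c.m, c.pair_channels
        block = 0
        while True:
            out_ch = c.conv_channels[min(block, len(c.conv_channels) - 1)]
            if length < c.conv_kernel + c.pool - 1:
                if block == 0:
                    raise ValueError(f"m={c.m} too short for the conv/pool stack")
                break
            conv = Conv1D(ch, out_ch, c.conv_kernel, rng, activation="relu", dtype=dt)
            pool = AvgPool1D(c.pool)
            length = pool.out_len(conv.out_len(length))
            ch = out_ch
            self.conv_stack += [conv, pool]
            block += 1
            if length <= c.max_conv_len:
                break
        self.flat_len = length * ch
        self.geno_dense = Dense(self.flat_len, c.n_features, rng, dtype=dt)
        # --- branch 2: spatial scores from the locations table
        self.loc1 = Dense(7, c.loc_hidden, rng, activation="relu", dtype=dt)
        self.loc2 = Dense(c.loc_hidden, c.n_features, rng, activation="relu", dtype=dt)
        # --- combiner (Eq-style pair aggregation) and output stack f
        self.W = Param(_glorot_like(rng, c.n_features, c.combiner_hidden).astype(dt))
        self.b = Param(np.zeros(c.combiner_hidden, dtype=dt))
        self.f1 = Dense(c.combiner_hidden, c.f_hidden, rng, activation="relu", dtype=dt)
        self.f2 = Dense(c.f_hidden, 2, rng, dtype=dt)
        self._cache: dict = {}

    # -- parameters ---------------------------------------------------------

    @property
    def branch1_params(self):
        out = []
        for layer in self.conv_stack:
            out += layer.params
        return out + self.geno_dense.params

    @property
    def params(self):
        return (self.branch1_params + self.loc1.params + self.loc2.params
                + [self.W, self.b] + self.f1.params + self.f2.params)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    # -- forward ------------------------------------------------------------

    def extract_pair_features(self, pair_x: np.ndarray) -> np.ndarray:
        """(N_pairs, m, channels) -> (N_pairs, F), shared weights across pairs."""
        h = pair_x
        for layer in self.conv_stack:
            h = layer.forward(h)
        h = h.reshape(h.shape[0], -1)
        return self.geno_dense.forward(h)

    def spatial_scores(self, loc_table: np.ndarray) -> np.ndarray:
        """(rows, 7) -> (rows, F) non-negative scores (two dense layers + ReLU)."""
        return self.loc2.forward(self.loc1.forward(loc_table))

    def combine(self, G: np.ndarray, S: np.ndarray) -> np.ndarray:
        """Batched pair aggregation.

        G: (B, k, F); S: (B, w^2, k, F).  Returns (B, w^2, 2).  Equals the
        literal per-cell/per-pair loop up to float associativity.
        """
        T = G[:, None, :, :] * S
        Z = T @ self.W.value + self.b.value
        A = relu(Z)
        scale = 1.0 / T.shape[2] if self.config.normalize_pairs else 1.0
        U = A.sum(axis=2) * scale
        Y = self.f2.forward(self.f1.forward(U))
        self._cache.update(T=T, Z=Z, S=S, G=G, scale=scale)
        return Y

    def forward(self, pair_x: np.ndarray, loc_table: np.ndarray) -> np.ndarray:
        """Full forward pass.

        pair_x: (B, k, m, ch); loc_table: (B, w^2, k, 7) -> (B, w, w, 2).
        """
        B, k, m, ch = pair_x.shape
        w = self.config.w
        dt = self.config.np_dtype
        pair_x = np.ascontiguousarray(pair_x, dtype=dt)
        loc_table = np.ascontiguousarray(loc_table, dtype=dt)
        G = self.extract_pair_features(pair_x.reshape(B * k, m, ch)).reshape(B, k, -1)
        S = self.spatial_scores(loc_table.reshape(-1, 7)).reshape(B, w * w, k, -1)
        Y = self.combine(G, S)
        return Y.reshape(B, w, w, 2)

    # -- backward -----------------------------------------------------------

    def backward(self, dY: np.ndarray, extract_mask: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients for a batch.

        dY: (B, w, w, 2) loss gradient.  ``extract_mask`` (B, k) stops
        branch-1 gradients at pairs outside the k_extract subset; the
        locations branch and combiner always see every pair.
        """
        B = dY.shape[0]
        w = self.config.w
        T, Z, S, G = (self._cache[k] for k in ("T", "Z", "S", "G"))
        dYf = dY.reshape(B, w * w, 2).astype(self.config.np_dtype, copy=False)
        dU = self.f1.backward(self.f2.backward(dYf)) * self._cache["scale"]
        dZ = dU[:, :, None, :] * (Z > 0)  # sum over pairs broadcasts back
        dZ2 = dZ.reshape(-1, dZ.shape[-1])
        T2 = T.reshape(-1, T.shape[-1])
        self.W.grad += T2.T @ dZ2
        self.b.grad += dZ2.sum(axis=0)
        dT = dZ @ self.W.value.T
        dS = dT * G[:, None, :, :]
        dG = (dT * S).sum(axis=1)
        # branch 2 (all pairs)
        dLoc = self.loc1.backward(self.loc2.backward(dS.reshape(-1, dS.shape[-1])))
        del dLoc
        # branch 1 (gradient-active pairs only)
        if extract_mask is not None:
            dG = dG * extract_mask[:, :, None]
        dFlat = self.geno_dense.backward(dG.reshape(-1, dG.shape[-1]))
        h = dFlat.reshape(dFlat.shape[0], *self._conv_out_shape)
        for layer in reversed(self.conv_stack):
            h = layer.backward(h)

    @property
    def _conv_out_shape(self):
        # length x channels right before flattening
        ch = self.config.pair_channels
        length = self.config.m
        for layer in self.conv_stack:
            length = layer.out_len(length)
            if isinstance(layer, Conv1D):
                ch = layer.c_out
        return (length, ch)

    # -- prediction ---------------------------------------------------------

    def predict_map(self, genotypes: np.ndarray, locations: np.ndarray,
                    pairs: np.ndarray | None = None,
                    rng: np.random.Generator | None = None,
                    k_init: int | None = None) -> np.ndarray:
        """One forward pass -> (w, w, 2) map on the preprocessed scale."""
        c = self.config
        n = locations.shape[0]
        if genotypes.shape[1] != c.m or n != c.n:
            raise ValueError("dataset dimensions do not match the built model")
        if pairs is None:
            k = k_init or min(c.n * (c.n - 1) // 2, 450)
            pairs, _ = enumerate_pairs(n, PairSubsetConfig(k, k),
                                       rng or np.random.default_rng(0))
        px = pair_input(genotypes, pairs, c.phased, c.pair_encoding)[None]
        lt = build_locations_table(locations, pairs, c.w)[None].reshape(
            1, c.w * c.w, pairs.shape[0], 7)
        return self.forward(px, lt)[0]

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """JSON checkpoint: full config + flattened weights (text format)."""
        state = {
            "config": asdict(self.config),
            "weights": [p.value.tolist() for p in self.params],
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "MapNN":
        state = json.loads(Path(path).read_text())
        cfg = state["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        model = cls(ModelConfig(**cfg), np.random.default_rng(0))
        for p, w in zip(model.params, state["weights"]):
            p.value[...] = np.asarray(w, dtype=float).reshape(p.value.shape)
        return model


def _glorot_like(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))
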