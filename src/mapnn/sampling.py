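"""Choosing which individuals' genotypes and coordinates enter a dataset.

Three strategies: uniform over living individuals, a spatial grid with a
fixed quota per cell, and "fixed" target coordinates that mirror an
empirical sampling scheme (one individual near each target, with a
doubling search radius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import PopulationState

__all__ = [
    "SamplingScheme",
    "SampleSet",
    "sample_uniform",
    "sample_grid",
    "sample_near_locations",
    "draw_sample",
]


@dataclass
class SampleSet:
    """Indices into a population plus the selected coordinates."""

    indices: np.ndarray      # positions within the PopulationState arrays
    locations: np.ndarray    # (n, 2)

    @property
    def n(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class SamplingScheme:
    mode: str = "uniform"                 # uniform | grid | fixed
    n: int = 100
    grid_size: int = 5                    # grid mode
    per_cell: int = 4                     # grid mode
    target_coords: tuple = ()             # fixed mode
    initial_radius_fraction: float = 0.02  # fixed mode
    nearest: bool = False                 # fixed mode: take nearest instead of random

    def __post_init__(self):
        if self.mode not in ("uniform", "grid", "fixed"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "grid" and self.n != self.grid_size**2 * self.per_cell:
            object.__setattr__(self, "n", self.grid_size**2 * self.per_cell)


def sample_uniform(pop: PopulationState, n: int, rng: np.random.Generator) -> SampleSet:
    """n distinct individuals, uniform without replacement."""
    if pop.size < n:
        raise ValueError(f"population of {pop.size} cannot yield {n} samples")
    idx = rng.choice(pop.size, size=n, replace=False)
    return SampleSet(idx.astype(np.int64), pop.locations()[idx])


def sample_grid(pop: PopulationState, grid_size: int, per_cell: int,
                rng: np.random.Generator, habitat_width: float) -> SampleSet:
    """Exactly ``per_cell`` individuals uniform within each sampling cell.

    Deficient cells raise, naming the cell: silent under-sampling would
    bias the spatial balance the strategy exists to provide.
    """
    cell = habitat_width / grid_size
    ix = np.minimum((pop.x / cell).astype(np.int64), grid_size - 1)
    iy = np.minimum((pop.y / cell).astype(np.int64), grid_size - 1)
    chosen = []
    for cy in range(grid_size):
        for cx in range(grid_size):
            here = np.nonzero((ix == cx) & (iy == cy))[0]
            if here.size < per_cell:
                raise ValueError(
                    f"sampling cell ({cx}, {cy}) holds {here.size} < {per_cell} individuals")
            chosen.append(rng.choice(here, size=per_cell, replace=False))
    idx = np.concatenate(chosen).astype(np.int64)
    return SampleSet(idx, pop.locations()[idx])


def sample_near_locations(pop: PopulationState, target_coords: np.ndarray,
                          rng: np.random.Generator, habitat_width: float,
                          initial_radius_fraction: float = 0.02,
                          nearest: bool = False) -> SampleSet:
    """One distinct individual per target coordinate.

    The search radius starts at ``initial_radius_fraction`` of the map
    width and doubles until an unclaimed candidate exists.  By default a
    random in-radius candidate is taken; ``nearest`` switches to the
    closest one.  Targets are processed in input order.
    """
    targets = np.atleast_2d(np.asarray(target_coords, dtype=float))
    if pop.size < len(targets):
        raise ValueError(f"population of {pop.size} cannot cover {len(targets)} targets")
    taken = np.zeros(pop.size, dtype=bool)
    locs = pop.locations()
    out = []
    for t in targets:
        d = np.hypot(locs[:, 0] - t[0], locs[:, 1] - t[1])
        r = initial_radius_fraction * habitat_width
        while True:
            cand = np.nonzero((d <= r) & ~taken)[0]
            if cand.size:
                break
            r *= 2.0
        pick = cand[np.argmin(d[cand])] if nearest else rng.choice(cand)
        taken[pick] = True
        out.append(pick)
    idx = np.asarray(out, dtype=np.int64)
    return SampleSet(idx, locs[idx])


def draw_sample(pop: PopulationState, scheme: SamplingScheme,
                rng: np.random.Generator, habitat_width: float) -> SampleSet:
    """Dispatch on the configured sampling mode."""
    if scheme.mode == "uniform":
        return sample_uniform(pop, scheme.n, rng)
    if scheme.mode == "grid":
        return sample_grid(pop, scheme.grid_size, scheme.per_cell, rng, habitat_width)
    return sample_near_locations(pop, np.asarray(scheme.target_coords, dtype=float),
                                 rng, habitat_width, scheme.initial_radius_fraction,
                                 scheme.nearest)
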