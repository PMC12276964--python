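"""Continuous-space, individual-based forward simulator.

Implements an overlapping-generations life cycle on a demographic map:
each cycle is reproduction (Gaussian mate choice truncated at 3*sigma_m,
Poisson(1/L) offspring per focal), natal dispersal (Gaussian with per-axis
SD sigma_f, offspring proposed outside the habitat are not produced), and
competition-based mortality (survival decreasing in the truncated-Gaussian
interaction sum eta relative to local carrying capacity K).  Individuals
are hermaphroditic and sessile after settling.

Local map parameters are bilinearly interpolated between cell centers.
The dispersal channel of the input map holds the *effective* sigma — the
RMS per-axis distance from an offspring to a uniformly chosen parent —
and the simulator works back to the natal-dispersal component sigma_f via
``sigma^2 = sigma_f^2 + sigma_m^2 / 2``.

Neighbor sums use an exact uniform-grid bucket index (no approximation
beyond the stated 3-SD kernel truncation); the hot loops are JIT-compiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .maps import DemographicMap

__all__ = [
    "SimParams",
    "GenomeMap",
    "PopulationState",
    "RealizedMaps",
    "AncestryTables",
    "SimulationExtinct",
    "SimResult",
    "sigma_from_components",
    "sigma_f_from_target",
    "interpolate_map_at",
    "local_interaction_strength",
    "choose_mate",
    "survival_probability",
    "initial_population",
    "reproduce_and_disperse",
    "record_realized_maps",
    "run_simulation",
]

# Mass of a 2-D Gaussian kernel inside its 3-SD truncation radius.
KERNEL_TRUNCATION_MASS = 1.0 - math.exp(-4.5)


class SimulationExtinct(RuntimeError):
    def __init__(self, cycle: int):
        super().__init__(f"population extinct at cycle {cycle}")
        self.cycle = cycle


@dataclass(frozen=True)
class GenomeMap:
    """Genome as independent segments with per-segment recombination rates.

    ``lengths`` are in bp; ``rates`` are per bp per generation.  Segment
    boundaries recombine with probability 1/2 (independent assortment).
    """

    lengths: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self):
        if len(self.lengths) != len(self.rates):
            raise ValueError("lengths and rates differ in length")

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.lengths)[:-1]])

    @classmethod
    def single(cls, length: float, rate: float) -> "GenomeMap":
        return cls((float(length),), (float(rate),))

    def sample_breakpoints(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoint positions for ``n`` transmissions.

        Returns (positions, transmission index), sorted within transmission.
        Within-segment crossovers are Poisson; each internal boundary adds a
        breakpoint with probability 1/2.
        """
        pos_parts, tid_parts = [], []
        starts = self.starts
        for s, L, r in zip(starts, self.lengths, self.rates):
            k = rng.poisson(r * L, size=n)
            tot = int(k.sum())
            if tot:
                tid = np.repeat(np.arange(n), k)
                pos = rng.uniform(s, s + L, size=tot)
                pos_parts.append(pos)
                tid_parts.append(tid)
        for s in starts[1:]:
            hit = np.nonzero(rng.random(n) < 0.5)[0]
            if hit.size:
                pos_parts.append(np.full(hit.size, s))
                tid_parts.append(hit)
        if not pos_parts:
            return np.empty(0), np.empty(0, dtype=np.int64)
        pos = np.concatenate(pos_parts)
        tid = np.concatenate(tid_parts).astype(np.int64)
        order = np.lexsort((pos, tid))
        return pos[order], tid[order]


@dataclass
class SimParams:
    """Life-cycle parameters.  Kernels are truncated at 3x their SD."""

    sigma_m: float = 1.0          # mate-choice kernel SD
    sigma_c: float = 1.0          # competition kernel SD
    L: float = 4.0                # rough mean lifetime at stationarity
    n_cycles: int = 10_000
    burn_in: int = 250
    genome_length: float = 1e8    # bp (single segment unless genome_map given)
    recomb_rate: float = 1e-8     # per bp per generation
    competition_scale: float = 0.225  # c in p = 1/(1 + c*eta/K); see module docs
    genome_map: GenomeMap | None = None

    def __post_init__(self):
        if self.burn_in >= self.n_cycles:
            raise ValueError("burn_in must be < n_cycles")
        if self.sigma_m <= 0 or self.sigma_c <= 0:
            raise ValueError("kernel SDs must be positive")
        if self.genome_map is None:
            self.genome_map = GenomeMap.single(self.genome_length, self.recomb_rate)


@dataclass
class PopulationState:
    """Alive individuals: continuous locations plus global ids and birth cycles."""

    x: np.ndarray
    y: np.ndarray
    gid: np.ndarray          # global individual index (stable across the run)
    birth_cycle: np.ndarray

    @property
    def size(self) -> int:
        return self.x.size

    def locations(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)


@dataclass
class RealizedMaps:
    """Per-cell density and dispersal actually observed post burn-in."""

    density: np.ndarray     # (g, g) individuals per unit area (time-averaged)
    dispersal: np.ndarray   # (g, g) realized sigma; NaN where no events
    counts: np.ndarray      # (g, g) dispersal axis-component counts


@dataclass
class AncestryTables:
    """Raw parentage + transmission records, convertible to tskit tables."""

    mother: np.ndarray        # (M,) global id of mother, -1 for founders
    father: np.ndarray
    birth_cycle: np.ndarray   # (M,) founders carry -1
    edge_left: np.ndarray
    edge_right: np.ndarray
    edge_parent_node: np.ndarray   # node id = 2*gid + copy
    edge_child_node: np.ndarray
    sequence_length: float


@dataclass
class SimResult:
    population: PopulationState
    realized: RealizedMaps | None
    ancestry: AncestryTables | None
    final_census: int
    trajectory: np.ndarray   # census size per cycle


# ---------------------------------------------------------------------------
# elementary operations


def sigma_from_components(sigma_f: float, sigma_m: float) -> float:
    """Effective sigma: RMS per-axis offspring distance to a random parent.

    The offspring-mother displacement has per-axis variance sigma_f^2; the
    offspring-father displacement adds the mate distance (variance sigma_m^2
    per axis); each parent is chosen with probability 1/2.
    """
    if sigma_f < 0 or sigma_m < 0:
        raise ValueError("components must be >= 0")
    return math.sqrt(sigma_f**2 + sigma_m**2 / 2.0)


def sigma_f_from_target(sigma: np.ndarray | float, sigma_m: float) -> np.ndarray | float:
    """Invert sigma_from_components for the natal-dispersal component."""
    v = np.square(sigma) - sigma_m**2 / 2.0
    if np.any(np.asarray(v) < 0):
        raise ValueError("target sigma below the mating-kernel floor sigma_m/sqrt(2)")
    return np.sqrt(v)


def _bilinear(values: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of cell-center values, clamped at the edges."""
    w = values.shape[0]
    gx = np.clip(np.asarray(x, dtype=float) - 0.5, 0.0, w - 1.0)
    gy = np.clip(np.asarray(y, dtype=float) - 0.5, 0.0, w - 1.0)
    ix0 = np.minimum(gx.astype(np.int64), w - 2) if w > 1 else np.zeros_like(gx, np.int64)
    iy0 = np.minimum(gy.astype(np.int64), w - 2) if w > 1 else np.zeros_like(gy, np.int64)
    fx = gx - ix0
    fy = gy - iy0
    v00 = values[iy0, ix0]
    v01 = values[iy0, ix0 + 1] if w > 1 else v00
    v10 = values[iy0 + 1, ix0] if w > 1 else v00
    v11 = values[iy0 + 1, ix0 + 1] if w > 1 else v00
    return (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
            + v10 * (1 - fx) * fy + v11 * fx * fy)


def interpolate_map_at(dmap: DemographicMap, x: np.ndarray | float,
                       y: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """(sigma, K) at continuous locations; errors outside the habitat."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    w = dmap.width
    if np.any((x < 0) | (x > w) | (y < 0) | (y > w)):
        raise ValueError("location outside the habitat square")
    if dmap.habitat_mask is not None:
        ix = np.minimum(x.astype(np.int64), w - 1)
        iy = np.minimum(y.astype(np.int64), w - 1)
        if not dmap.habitat_mask[iy, ix].all():
            raise ValueError("location outside the habitat mask")
    return _bilinear(dmap.dispersal.values, x, y), _bilinear(dmap.density.values, x, y)


def survival_probability(eta: np.ndarray | float, K_local: np.ndarray | float,
                         L: float, c: float = 0.225) -> np.ndarray | float:
    """p = 1 / (1 + c * eta / K): 1 at eta = 0, decreasing in crowding.

    ``c`` calibrates how the interaction sum maps onto the carrying
    capacity; the default is set so that a uniform population equilibrates
    with realized density slightly below K (see the methods note).
    """
    if np.any(np.asarray(K_local) <= 0):
        raise ValueError("nonpositive local carrying capacity (uninhabitable cell)")
    del L  # lifetime enters through fecundity; kept in the signature for clarity
    return 1.0 / (1.0 + c * np.asarray(eta, dtype=float) / np.asarray(K_local, dtype=float))


# ---------------------------------------------------------------------------
# bucketed neighbor kernels (exact truncated sums)


@njit(cache=True, fastmath=True)
def _bucketize(x, y, h, nb):
    n = x.size
    bucket = np.empty(n, np.int64)
    for i in range(n):
        bx = min(int(x[i] / h), nb - 1)
        by = min(int(y[i] / h), nb - 1)
        bucket[i] = by * nb + bx
    counts = np.zeros(nb * nb + 1, np.int64)
    for i in range(n):
        counts[bucket[i] + 1] += 1
    for b in range(1, nb * nb + 1):
        counts[b] += counts[b - 1]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        order[fill[bucket[i]]] = i
        fill[bucket[i]] += 1
    return counts, order


@njit(cache=True, fastmath=True)
def _eta_sums(x, y, h, nb, starts, order, sigma_c):
    """Truncated-Gaussian neighbor sums; each unordered pair visited once."""
    n = x.size
    r2max = 9.0 * sigma_c * sigma_c
    inv2s2 = 1.0 / (2.0 * sigma_c * sigma_c)
    out = np.zeros(n)
    for by in range(nb):
        for bx in range(nb):
            b = by * nb + bx
            b0, b1 = starts[b], starts[b + 1]
            # pairs within the bucket
            for p in range(b0, b1):
                i = order[p]
                xi, yi = x[i], y[i]
                for q in range(p + 1, b1):
                    j = order[q]
                    dx = x[j] - xi
                    dy = y[j] - yi
                    d2 = dx * dx + dy * dy
                    if d2 <= r2max:
                        wgt = math.exp(-d2 * inv2s2)
                        out[i] += wgt
                        out[j] += wgt
            # pairs with half of the neighboring buckets (the other half is
            # covered when those buckets take their turn)
            for off in range(4):
                if off == 0:
                    nbx_, nby_ = bx + 1, by - 1
                elif off == 1:
                    nbx_, nby_ = bx + 1, by
                elif off == 2:
                    nbx_, nby_ = bx + 1, by + 1
                else:
                    nbx_, nby_ = bx, by + 1
                if nbx_ < 0 or nbx_ >= nb or nby_ < 0 or nby_ >= nb:
                    continue
                c = nby_ * nb + nbx_
                c0, c1 = starts[c], starts[c + 1]
                for p in range(b0, b1):
                    i = order[p]
                    xi, yi = x[i], y[i]
                    for q in range(c0, c1):
                        j = order[q]
                        dx = x[j] - xi
                        dy = y[j] - yi
                        d2 = dx * dx + dy * dy
                        if d2 <= r2max:
                            wgt = math.exp(-d2 * inv2s2)
                            out[i] += wgt
                            out[j] += wgt
    return out


@njit(cache=True, fastmath=True)
def _choose_mates_kernel(focal, x, y, h, nb, starts, order, sigma_m, u):
    """Weighted mate draw per focal: Gaussian weight, truncated at 3*sigma_m.

    ``u`` holds one uniform deviate per focal; the categorical draw is made
    by a two-pass cumulative scan over in-radius neighbors.
    """
    m = focal.size
    out = np.full(m, -1, np.int64)
    r2max = 9.0 * sigma_m * sigma_m
    inv2s2 = 1.0 / (2.0 * sigma_m * sigma_m)
    for fi in range(m):
        i = focal[fi]
        bx = min(int(x[i] / h), nb - 1)
        by = min(int(y[i] / h), nb - 1)
        total = 0.0
        for dby in range(-1, 2):
            nby_ = by + dby
            if nby_ < 0 or nby_ >= nb:
                continue
            for dbx in range(-1, 2):
                nbx_ = bx + dbx
                if nbx_ < 0 or nbx_ >= nb:
                    continue
                b = nby_ * nb + nbx_
                for p in range(starts[b], starts[b + 1]):
                    j = order[p]
                    if j == i:
                        continue
                    dx = x[j] - x[i]
                    dy = y[j] - y[i]
                    d2 = dx * dx + dy * dy
                    if d2 <= r2max:
                        total += math.exp(-d2 * inv2s2)
        if total <= 0.0:
            continue
        target = u[fi] * total
        acc = 0.0
        done = False
        for dby in range(-1, 2):
            if done:
                break
            nby_ = by + dby
            if nby_ < 0 or nby_ >= nb:
                continue
            for dbx in range(-1, 2):
                if done:
                    break
                nbx_ = bx + dbx
                if nbx_ < 0 or nbx_ >= nb:
                    continue
                b = nby_ * nb + nbx_
                for p in range(starts[b], starts[b + 1]):
                    j = order[p]
                    if j == i:
                        continue
                    dx = x[j] - x[i]
                    dy = y[j] - y[i]
                    d2 = dx * dx + dy * dy
                    if d2 <= r2max:
                        acc += math.exp(-d2 * inv2s2)
                        if acc >= target:
                            out[fi] = j
                            done = True
                            break
        if not done:  # float round-off on the last neighbor
            out[fi] = j
    return out


def _grid(x: np.ndarray, y: np.ndarray, radius: float, w: float):
    h = max(radius, 1e-9)
    nb = max(int(math.ceil(w / h)), 1)
    starts, order = _bucketize(x, y, h, nb)
    return h, nb, starts, order


def local_interaction_strength(positions: np.ndarray, sigma_c: float,
                               habitat_width: float | None = None) -> np.ndarray:
    """eta for every individual: truncated-Gaussian density of neighbors.

    The kernel is normalized by 1/(2 pi sigma_c^2) so that for a uniform
    field of intensity rho, E[eta] ~= 0.9889 * rho (the 3-SD mass).
    """
    x = np.ascontiguousarray(positions[:, 0], dtype=float)
    y = np.ascontiguousarray(positions[:, 1], dtype=float)
    if x.size == 0:
        return np.empty(0)
    w = habitat_width if habitat_width is not None else max(x.max(), y.max()) + 1e-9
    h, nb, starts, order = _grid(x, y, 3.0 * sigma_c, w)
    return _eta_sums(x, y, h, nb, starts, order, sigma_c) / (2.0 * math.pi * sigma_c**2)


def choose_mate(positions: np.ndarray, focal: int | np.ndarray, sigma_m: float,
                rng: np.random.Generator, habitat_width: float | None = None) -> np.ndarray:
    """Mate index per focal (-1 when no neighbor lies within 3*sigma_m)."""
    x = np.ascontiguousarray(positions[:, 0], dtype=float)
    y = np.ascontiguousarray(positions[:, 1], dtype=float)
    focal = np.atleast_1d(np.asarray(focal, dtype=np.int64))
    w = habitat_width if habitat_width is not None else max(x.max(), y.max()) + 1e-9
    h, nb, starts, order = _grid(x, y, 3.0 * sigma_m, w)
    u = rng.random(focal.size)
    return _choose_mates_kernel(focal, x, y, h, nb, starts, order, sigma_m, u)


# ---------------------------------------------------------------------------
# population initialization and the cycle


def initial_population(dmap: DemographicMap, rng: np.random.Generator) -> PopulationState:
    """Mean-K * w^2 individuals placed uniformly on the habitable area."""
    w = dmap.width
    n0 = int(round(float(dmap.density.values.mean()) * w * w))
    if n0 <= 0:
        raise ValueError("initial population size is zero")
    if dmap.habitat_mask is None:
        x = rng.uniform(0, w, n0)
        y = rng.uniform(0, w, n0)
    else:
        xs, ys = [], []
        need = n0
        while need > 0:
            cx = rng.uniform(0, w, 2 * need + 16)
            cy = rng.uniform(0, w, 2 * need + 16)
            ok = dmap.habitat_mask[np.minimum(cy.astype(np.int64), w - 1),
                                   np.minimum(cx.astype(np.int64), w - 1)]
            xs.append(cx[ok][:need])
            ys.append(cy[ok][:need])
            need = n0 - sum(a.size for a in xs)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    gid = np.arange(n0, dtype=np.int64)
    return PopulationState(x, y, gid, np.full(n0, -1, np.int64))


def reproduce_and_disperse(state: PopulationState, dmap: DemographicMap,
                           params: SimParams, rng: np.random.Generator,
                           next_gid: int, cycle: int):
    """One round of mating + offspring placement against the current adults.

    Returns (offspring_x, offspring_y, mother_idx, father_idx) as indices
    into ``state``; offspring proposed outside the habitat (or mask) are
    discarded without retry.
    """
    n = state.size
    w = dmap.width
    n_off = rng.poisson(1.0 / params.L, n)
    focal = np.nonzero(n_off > 0)[0]
    if focal.size == 0:
        e = np.empty(0)
        return e, e, np.empty(0, np.int64), np.empty(0, np.int64)
    mates = choose_mate(state.locations(), focal, params.sigma_m, rng, habitat_width=w)
    ok = mates >= 0
    focal, mates = focal[ok], mates[ok]
    counts = n_off[focal]
    mother = np.repeat(focal, counts)
    father = np.repeat(mates, counts)
    sig_loc = _bilinear(dmap.dispersal.values, state.x[mother], state.y[mother])
    sigma_f = sigma_f_from_target(np.maximum(sig_loc, params.sigma_m / math.sqrt(2.0)),
                                  params.sigma_m)
    ox = state.x[mother] + rng.normal(0.0, 1.0, mother.size) * sigma_f
    oy = state.y[mother] + rng.normal(0.0, 1.0, mother.size) * sigma_f
    keep = (ox >= 0) & (ox < w) & (oy >= 0) & (oy < w)
    if dmap.habitat_mask is not None:
        ix = np.clip(ox.astype(np.int64), 0, w - 1)
        iy = np.clip(oy.astype(np.int64), 0, w - 1)
        keep &= dmap.habitat_mask[iy, ix]
    del next_gid, cycle
    return ox[keep], oy[keep], mother[keep], father[keep]


class _RealizedAccumulator:
    def __init__(self, g: int, w: int):
        self.g = g
        self.w = w
        self.cell = float(w) / g
        self.density_sum = np.zeros((g, g))
        self.n_census = 0
        self.disp_ss = np.zeros((g, g))
        self.disp_n = np.zeros((g, g), dtype=np.int64)

    def add_census(self, x: np.ndarray, y: np.ndarray) -> None:
        g = self.g
        ix = np.minimum((x / self.cell).astype(np.int64), g - 1)
        iy = np.minimum((y / self.cell).astype(np.int64), g - 1)
        np.add.at(self.density_sum, (iy, ix), 1.0)
        self.n_census += 1

    def add_births(self, ox, oy, dmx, dmy, dfx, dfy) -> None:
        g = self.g
        ix = np.minimum((ox / self.cell).astype(np.int64), g - 1)
        iy = np.minimum((oy / self.cell).astype(np.int64), g - 1)
        ss = dmx**2 + dmy**2 + dfx**2 + dfy**2
        np.add.at(self.disp_ss, (iy, ix), ss)
        np.add.at(self.disp_n, (iy, ix), 4)

    def finalize(self) -> RealizedMaps:
        area = self.cell**2
        dens = self.density_sum / max(self.n_census, 1) / area
        with np.errstate(invalid="ignore", divide="ignore"):
            disp = np.sqrt(self.disp_ss / self.disp_n)
        disp[self.disp_n == 0] = np.nan
        return RealizedMaps(dens, disp, self.disp_n.copy())


def record_realized_maps(natal_x, natal_y, parent_dx, parent_dy,
                         grid_size: int, habitat_width: float) -> RealizedMaps:
    """Realized dispersal map from an explicit event list.

    Each event is one offspring-to-parent displacement vector; both axis
    components are pooled into the per-natal-cell RMS.  Density is left at
    zero (use ``run_simulation`` for the time-averaged census).
    """
    cell = float(habitat_width) / grid_size
    ix = np.minimum((np.asarray(natal_x, float) / cell).astype(np.int64), grid_size - 1)
    iy = np.minimum((np.asarray(natal_y, float) / cell).astype(np.int64), grid_size - 1)
    ss = np.zeros((grid_size, grid_size))
    n = np.zeros((grid_size, grid_size), dtype=np.int64)
    np.add.at(ss, (iy, ix), np.asarray(parent_dx, float) ** 2 + np.asarray(parent_dy, float) ** 2)
    np.add.at(n, (iy, ix), 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.sqrt(ss / n)
    disp[n == 0] = np.nan
    return RealizedMaps(np.zeros((grid_size, grid_size)), disp, n)


class _AncestryRecorder:
    def __init__(self, genome: GenomeMap, n_founders: int):
        self.genome = genome
        self.mother = [np.full(n_founders, -1, np.int64)]
        self.father = [np.full(n_founders, -1, np.int64)]
        self.birth = [np.full(n_founders, -1, np.int64)]
        self.el, self.er, self.ep, self.ec = [], [], [], []

    def record(self, rng: np.random.Generator, child_gid, mother_gid, father_gid, cycle):
        nb = child_gid.size
        self.mother.append(mother_gid.astype(np.int64))
        self.father.append(father_gid.astype(np.int64))
        self.birth.append(np.full(nb, cycle, np.int64))
        G = self.genome.total_length
        # 2 transmissions per child: maternal copy then paternal copy
        par = np.empty(2 * nb, np.int64)
        par[0::2] = mother_gid
        par[1::2] = father_gid
        child_nodes = np.empty(2 * nb, np.int64)
        child_nodes[0::2] = 2 * child_gid
        child_nodes[1::2] = 2 * child_gid + 1
        pos, tid = self.genome.sample_breakpoints(rng, 2 * nb)
        k = np.bincount(tid, minlength=2 * nb)
        start_hap = rng.integers(0, 2, size=2 * nb)
        nseg = k + 1
        seg_tid = np.repeat(np.arange(2 * nb), nseg)
        seg_rank = np.arange(seg_tid.size) - np.repeat(np.cumsum(nseg) - nseg, nseg)
        lefts = np.zeros(seg_tid.size)
        rights = np.full(seg_tid.size, G)
        if pos.size:
            is_internal_left = seg_rank > 0
            lefts[is_internal_left] = pos
            rights[np.nonzero(is_internal_left)[0] - 1] = pos
        hap = (start_hap[seg_tid] + seg_rank) % 2
        self.el.append(lefts)
        self.er.append(rights)
        self.ep.append(2 * par[seg_tid] + hap)
        self.ec.append(child_nodes[seg_tid])

    def finalize(self) -> AncestryTables:
        return AncestryTables(
            np.concatenate(self.mother), np.concatenate(self.father),
            np.concatenate(self.birth),
            np.concatenate(self.el) if self.el else np.empty(0),
            np.concatenate(self.er) if self.er else np.empty(0),
            np.concatenate(self.ep) if self.ep else np.empty(0, np.int64),
            np.concatenate(self.ec) if self.ec else np.empty(0, np.int64),
            self.genome.total_length,
        )


def run_simulation(dmap: DemographicMap, params: SimParams, rng: np.random.Generator,
                   record_realized: bool = True, record_ancestry: bool = False,
                   realized_grid: int | None = None,
                   event_log: "str | None" = None) -> SimResult:
    """Run the full reproduction -> dispersal -> mortality loop.

    Raises :class:`SimulationExtinct` if the population dies out.  Realized
    density/dispersal are accumulated for cycles after ``params.burn_in``.
    ``event_log`` (debug) writes one CSV row per birth: cycle, offspring id,
    natal location, and the displacement to each parent.
    """
    w = dmap.width
    log_fh = open(event_log, "w") if event_log else None
    if log_fh:
        log_fh.write("cycle,offspring_id,natal_x,natal_y,"
                     "mother_dx,mother_dy,father_dx,father_dy\n")
    state = initial_population(dmap, rng)
    recorder = _AncestryRecorder(params.genome_map, state.size) if record_ancestry else None
    acc = _RealizedAccumulator(realized_grid or w, w) if record_realized else None
    next_gid = state.size
    traj = np.zeros(params.n_cycles, dtype=np.int64)
    Kvals = dmap.density.values
    c = params.competition_scale
    for cycle in range(params.n_cycles):
        ox, oy, mo, fa = reproduce_and_disperse(state, dmap, params, rng, next_gid, cycle)
        nb = ox.size
        child_gid = np.arange(next_gid, next_gid + nb, dtype=np.int64)
        next_gid += nb
        if recorder is not None and nb:
            recorder.record(rng, child_gid, state.gid[mo], state.gid[fa], cycle)
        if acc is not None and cycle >= params.burn_in and nb:
            acc.add_births(ox, oy, ox - state.x[mo], oy - state.y[mo],
                           ox - state.x[fa], oy - state.y[fa])
        if log_fh and nb:
            rows = np.column_stack([np.full(nb, cycle), child_gid, ox, oy,
                                    ox - state.x[mo], oy - state.y[mo],
                                    ox - state.x[fa], oy - state.y[fa]])
            np.savetxt(log_fh, rows, delimiter=",", fmt="%.6g")
        allx = np.concatenate([state.x, ox])
        ally = np.concatenate([state.y, oy])
        allgid = np.concatenate([state.gid, child_gid])
        allbirth = np.concatenate([state.birth_cycle, np.full(nb, cycle, np.int64)])
        eta = local_interaction_strength(np.stack([allx, ally], axis=1),
                                         params.sigma_c, habitat_width=w)
        K_loc = _bilinear(Kvals, allx, ally)
        if np.any(K_loc <= 0):
            raise ValueError("individual reached an uninhabitable (K<=0) location")
        p = 1.0 / (1.0 + c * eta / K_loc)
        alive = rng.random(allx.size) < p
        state = PopulationState(allx[alive], ally[alive], allgid[alive], allbirth[alive])
        traj[cycle] = state.size
        # below two individuals no mating is possible and the survival rule
        # (eta = 0 for a loner) would preserve a dead end forever
        if state.size < 2:
            raise SimulationExtinct(cycle)
        if acc is not None and cycle >= params.burn_in:
            acc.add_census(state.x, state.y)
    if log_fh:
        log_fh.close()
    return SimResult(state, acc.finalize() if acc else None,
                     recorder.finalize() if recorder else None,
                     state.size, traj)
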