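"""Random demographic maps: simulator input and training targets.

A demographic map is a ``w x w x 2`` grid holding local dispersal rate
(sigma, distance units per generation) and carrying capacity (K,
individuals per unit area).  Maps are generated by splitting the square
habitat into a small number of segments with a random polynomial boundary
curve and assigning each segment a value drawn from a log-uniform prior.

Internally channel arrays are indexed ``[iy, ix]`` with ``iy`` increasing
northward, i.e. cell ``(iy, ix)`` has its center at continuous habitat
coordinates ``(ix + 0.5, iy + 0.5)`` in ``[0, w]^2``.  CSV serialization
writes the northern row first (row-major), so files read like a map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MapPrior",
    "MapChannel",
    "DemographicMap",
    "ViabilityFit",
    "draw_channel",
    "draw_map",
    "fit_boundary_polynomial",
    "assign_segments",
    "draw_segment_values",
    "apply_dihedral_transform",
    "dihedral_transform_array",
    "viability_correct",
    "calibrate_viability",
    "apply_habitat_mask",
    "read_mask",
    "save_map",
    "load_map",
    "render_png",
    "write_grid_csv",
    "read_grid_csv",
]


@dataclass(frozen=True)
class MapPrior:
    """Log-uniform prior range for one map channel."""

    p_min: float
    p_max: float
    channel: str  # "dispersal" or "density"

    def __post_init__(self) -> None:
        if not (0 < self.p_min < self.p_max):
            raise ValueError(f"require 0 < p_min < p_max, got ({self.p_min}, {self.p_max})")
        if self.channel not in ("dispersal", "density"):
            raise ValueError(f"unknown channel {self.channel!r}")

    def log_uniform(self, rng: np.random.Generator, low: float | None = None,
                    high: float | None = None) -> float:
        lo = self.p_min if low is None else low
        hi = self.p_max if high is None else high
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


@dataclass
class MapChannel:
    """One w x w channel of positive values plus its segment labelling."""

    width: int
    values: np.ndarray            # (w, w) positive floats
    segment_labels: np.ndarray    # (w, w) small ints, labels 0..n_segments-1
    degree: int = 0               # degree of the generating boundary curve (0 = flat)

    @property
    def n_segments(self) -> int:
        return int(len(np.unique(self.segment_labels)))


@dataclass
class DemographicMap:
    """Paired dispersal (sigma) and density (K) channels, optional habitat mask."""

    dispersal: MapChannel
    density: MapChannel
    habitat_mask: np.ndarray | None = None  # (w, w) booleans, True = habitable

    def __post_init__(self) -> None:
        if self.dispersal.width != self.density.width:
            raise ValueError("channel widths differ")
        if self.habitat_mask is not None:
            self.habitat_mask = np.asarray(self.habitat_mask, dtype=bool)
            if self.habitat_mask.shape != self.dispersal.values.shape:
                raise ValueError("mask shape does not match channels")

    @property
    def width(self) -> int:
        return self.dispersal.width

    def stacked(self) -> np.ndarray:
        """Return the (w, w, 2) array with channel 0 = dispersal, 1 = density."""
        return np.stack([self.dispersal.values, self.density.values], axis=-1)


@dataclass(frozen=True)
class ViabilityFit:
    """Linear fit log(sigma_min) = slope * log(K) + intercept, plus a safety boost."""

    slope: float
    intercept: float
    boost: float = 1.25

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.boost < 1:
            raise ValueError("boost must be >= 1")

    def sigma_min(self, K: np.ndarray | float) -> np.ndarray | float:
        return np.exp(self.slope * np.log(K) + self.intercept)

    def k_min(self, sigma: np.ndarray | float) -> np.ndarray | float:
        # invert sigma_min = exp(slope*log K + intercept)
        return np.exp((np.log(sigma) - self.intercept) / self.slope)


# ---------------------------------------------------------------------------
# generation


def fit_boundary_polynomial(points: Sequence[tuple[float, float]]) -> np.ndarray:
    """Interpolating polynomial through ``degree+1`` points.

    Returns coefficients highest-degree first (``np.polyval`` convention).
    Raises ValueError on duplicate x coordinates; the caller resamples.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) != len(x):
        raise ValueError("duplicate x-coordinates")
    deg = len(x) - 1
    # Vandermonde solve: exact interpolation, not least squares
    V = np.vander(x, deg + 1)
    return np.linalg.solve(V, y)


def assign_segments(width: int, curve: np.ndarray, max_segments: int = 3) -> np.ndarray:
    """Label each grid cell with a segment id given a boundary polynomial.

    Cells are first classified below/above the curve at their center
    ``(ix + 0.5, iy + 0.5)``; 4-connected components of that binary field
    become segments.  Components beyond ``max_segments`` (ordered by size)
    are merged into the kept component with the nearest centroid.
    """
    xc = np.arange(width) + 0.5
    yc = np.arange(width) + 0.5
    ycurve = np.polyval(curve, xc)  # curve height at each column center
    below = yc[:, None] < ycurve[None, :]  # (iy, ix)

    lab_b, nb = ndimage.label(below, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    lab_a, na = ndimage.label(~below, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    labels = np.where(below, lab_b - 1, nb + lab_a - 1)  # 0..nb+na-1

    n_comp = nb + na
    if n_comp <= max_segments:
        return _relabel_dense(labels)

    sizes = np.bincount(labels.ravel(), minlength=n_comp)
    order = np.argsort(-sizes, kind="stable")
    keep = order[:max_segments]
    iy, ix = np.indices(labels.shape)
    centroids = np.stack(
        [ndimage.mean(ix + 0.5, labels, index=np.arange(n_comp)),
         ndimage.mean(iy + 0.5, labels, index=np.arange(n_comp))], axis=1)
    remap = np.arange(n_comp)
    for comp in order[max_segments:]:
        d = np.linalg.norm(centroids[keep] - centroids[comp], axis=1)
        remap[comp] = keep[int(np.argmin(d))]
    return _relabel_dense(remap[labels])


def _relabel_dense(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 0..k-1 preserving first-appearance order."""
    _, dense = np.unique(labels, return_inverse=True)
    return dense.reshape(labels.shape).astype(np.int64)


def draw_segment_values(prior: MapPrior, n_segments: int, rng: np.random.Generator) -> list[float]:
    """Values for the segments of one channel.

    Flat maps get a single log-uniform value from the prior.  Otherwise the
    value range r is uniform on (p_min, p_max) (resampled until it fits
    inside the prior width), the minimum v_min is log-uniform on
    (p_min, p_max - r); two segments get {v_min, v_min + r} and any further
    segments get uniform values strictly inside (v_min, v_min + r).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments == 1:
        return [prior.log_uniform(rng)]
    span = prior.p_max - prior.p_min
    r = rng.uniform(prior.p_min, prior.p_max)
    while r >= span:
        r = rng.uniform(prior.p_min, prior.p_max)
    v_min = prior.log_uniform(rng, prior.p_min, prior.p_max - r)
    values = [v_min, v_min + r]
    for _ in range(n_segments - 2):
        values.append(float(rng.uniform(v_min, v_min + r)))
    return values


def draw_channel(prior: MapPrior, max_segments: int, rng: np.random.Generator,
                 width: int = 50) -> MapChannel:
    """Draw one random channel: random boundary curve, segment labelling, values."""
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    if width < 2:
        raise ValueError("width must be >= 2")
    degree = 0 if max_segments == 1 else int(rng.integers(0, 4))
    if degree == 0:
        v = prior.log_uniform(rng)
        return MapChannel(width, np.full((width, width), v), np.zeros((width, width), np.int64), 0)
    while True:
        pts = rng.uniform(0, width, size=(degree + 1, 2))
        try:
            coeffs = fit_boundary_polynomial(pts)
        except ValueError:  # duplicate x, resample (probability zero, but guarded)
            continue
        break
    labels = assign_segments(width, coeffs, max_segments)
    n_seg = int(labels.max()) + 1
    values = draw_segment_values(prior, n_seg, rng)
    perm = rng.permutation(n_seg)  # segments get values in random order
    grid = np.asarray(values, dtype=float)[perm][labels]
    return MapChannel(width, grid, labels, degree)


def draw_map(sigma_prior: MapPrior, k_prior: MapPrior, rng: np.random.Generator,
             width: int = 50, max_segments: int = 3,
             transform: bool = True) -> DemographicMap:
    """Draw the two channels independently, stack, and randomly flip/rotate."""
    d = draw_channel(sigma_prior, max_segments, rng, width)
    k = draw_channel(k_prior, max_segments, rng, width)
    m = DemographicMap(d, k)
    if transform:
        m = apply_dihedral_transform(m, rng)
    return m


# ---------------------------------------------------------------------------
# transforms


def dihedral_transform_array(arr: np.ndarray, element: int) -> np.ndarray:
    """Apply element 0..7 of the dihedral group of the square to a 2-D array.

    Elements 0..3 are rotations by 0/90/180/270 degrees; 4..7 are the same
    rotations after a left-right flip.
    """
    if not 0 <= element < 8:
        raise ValueError("dihedral element must be in 0..7")
    out = np.fliplr(arr) if element >= 4 else arr
    return np.rot90(out, k=element % 4).copy()


def apply_dihedral_transform(dmap: DemographicMap, rng: np.random.Generator,
                             element: int | None = None) -> DemographicMap:
    """Random (or given) flip/rotation applied identically to channels and mask."""
    if dmap.width != dmap.dispersal.values.shape[1]:
        raise ValueError("map must be square")
    k = int(rng.integers(0, 8)) if element is None else element
    t = lambda a: dihedral_transform_array(a, k)
    d = MapChannel(dmap.width, t(dmap.dispersal.values), t(dmap.dispersal.segment_labels),
                   dmap.dispersal.degree)
    c = MapChannel(dmap.width, t(dmap.density.values), t(dmap.density.segment_labels),
                   dmap.density.degree)
    mask = t(dmap.habitat_mask) if dmap.habitat_mask is not None else None
    return DemographicMap(d, c, mask)


# ---------------------------------------------------------------------------
# viability correction (irregular-habitat mode)


def viability_correct(dmap: DemographicMap, fit: ViabilityFit, rng: np.random.Generator,
                      random_boost: bool = False) -> DemographicMap:
    """Raise cells whose (sigma, K) combination would not sustain a population.

    One channel is chosen uniformly at random to be boosted.  Offending
    cells (sigma below the fitted viability threshold sigma_min(K)) have
    the chosen channel raised to the threshold and multiplied by the boost
    factor (1.25 by default, or 1 + Uniform(0, 0.25) when ``random_boost``).
    """
    sig = dmap.dispersal.values.copy()
    K = dmap.density.values.copy()
    habit = np.ones_like(sig, dtype=bool) if dmap.habitat_mask is None else dmap.habitat_mask
    offending = habit & (sig < fit.sigma_min(np.where(habit, K, 1.0)))
    boost = (1.0 + rng.uniform(0, fit.boost - 1.0)) if random_boost else fit.boost
    if rng.integers(0, 2) == 0:
        sig = np.where(offending, fit.sigma_min(np.where(offending, K, 1.0)) * boost, sig)
    else:
        K = np.where(offending, fit.k_min(np.where(offending, sig, 1.0)) * boost, K)
    d = MapChannel(dmap.width, sig, dmap.dispersal.segment_labels, dmap.dispersal.degree)
    c = MapChannel(dmap.width, K, dmap.density.segment_labels, dmap.density.degree)
    return DemographicMap(d, c, dmap.habitat_mask)


def calibrate_viability(k_values: Sequence[float],
                        stable: Callable[[float, float], bool],
                        sigma_bounds: tuple[float, float],
                        tol: float = 1e-2, boost: float = 1.25) -> ViabilityFit:
    """Fit log(sigma_min) ~ log(K) by bisection on a stability predicate.

    ``stable(K, sigma)`` should report whether a uniform map with those
    parameters sustains a population (e.g. survives 500 cycles); a pilot
    grid of K values spanning the prior is recommended.
    """
    lo0, hi0 = sigma_bounds
    sig_mins = []
    for K in k_values:
        lo, hi = lo0, hi0
        if stable(K, lo):
            sig_mins.append(lo)
            continue
        if not stable(K, hi):
            raise ValueError(f"no stable sigma in bounds for K={K}")
        while hi / lo > 1 + tol:
            mid = float(np.sqrt(lo * hi))
            if stable(K, mid):
                hi = mid
            else:
                lo = mid
        sig_mins.append(hi)
    logk = np.log(np.asarray(k_values, dtype=float))
    logs = np.log(np.asarray(sig_mins, dtype=float))
    slope, intercept = np.polyfit(logk, logs, 1)
    return ViabilityFit(float(slope), float(intercept), boost)


def apply_habitat_mask(dmap: DemographicMap, mask: np.ndarray) -> DemographicMap:
    """Zero both channels outside the habitat and store the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dmap.dispersal.values.shape:
        raise ValueError("mask shape does not match map")
    if not mask.any():
        raise ValueError("mask excludes every cell: no habitat")
    d = MapChannel(dmap.width, np.where(mask, dmap.dispersal.values, 0.0),
                   dmap.dispersal.segment_labels, dmap.dispersal.degree)
    c = MapChannel(dmap.width, np.where(mask, dmap.density.values, 0.0),
                   dmap.density.segment_labels, dmap.density.degree)
    return DemographicMap(d, c, mask)


# ---------------------------------------------------------------------------
# serialization


def write_grid_csv(values: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Write a w x w grid as CSV, northern row first; optional JSON sidecar."""
    path = Path(path)
    np.savetxt(path, values[::-1], delimiter=",", fmt="%.10g")
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_grid_csv(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr[::-1].copy()


def save_map(dmap: DemographicMap, directory: str | Path, prefix: str = "map",
             meta: dict | None = None, png: bool = False) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = dict(meta or {})
    base["w"] = dmap.width
    for name, ch in (("dispersal", dmap.dispersal), ("density", dmap.density)):
        write_grid_csv(ch.values, directory / f"{prefix}_{name}.csv",
                       {**base, "channel": name})
    if dmap.habitat_mask is not None:
        write_grid_csv(dmap.habitat_mask.astype(int), directory / f"{prefix}_mask.csv")
    if png:
        render_png(dmap, directory / f"{prefix}.png")


def load_map(directory: str | Path, prefix: str = "map") -> DemographicMap:
    directory = Path(directory)
    sig = read_grid_csv(directory / f"{prefix}_dispersal.csv")
    K = read_grid_csv(directory / f"{prefix}_density.csv")
    w = sig.shape[0]
    mask_path = directory / f"{prefix}_mask.csv"
    mask = read_grid_csv(mask_path).astype(bool) if mask_path.exists() else None
    zeros = np.zeros((w, w), np.int64)
    return DemographicMap(MapChannel(w, sig, zeros), MapChannel(w, K, zeros), mask)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a habitat mask from a {0,1} CSV grid or an 8-bit PNG.

    PNG pixels with value > 127 (any channel) count as habitable; rows are
    flipped so the file's top row is the northern row, as for CSV grids.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return (arr[::-1] > 127).copy()
    return read_grid_csv(path).astype(bool)


def render_png(dmap: DemographicMap, path: str | Path,
               sigma_range: tuple[float, float] | None = None,
               k_range: tuple[float, float] | None = None) -> None:
    """8-bit PNG render: red channel scales with K, blue with sigma.

    Channels are scaled linearly over the given prior range (or the map's
    own range).  Rows are flipped so north is up.
    """
    from PIL import Image

    def scale(vals: np.ndarray, rng_: tuple[float, float] | None) -> np.ndarray:
        lo, hi = (vals.min(), vals.max()) if rng_ is None else rng_
        if hi <= lo:
            return np.full_like(vals, 255.0)
        return np.clip((vals - lo) / (hi - lo) * 255.0, 0, 255)

    w = dmap.width
    img = np.zeros((w, w, 3), dtype=np.uint8)
    img[..., 0] = scale(dmap.density.values, k_range)[::-1].astype(np.uint8)
    img[..., 2] = scale(dmap.dispersal.values, sigma_range)[::-1].astype(np.uint8)
    if dmap.habitat_mask is not None:
        img[~dmap.habitat_mask[::-1]] = 255  # out of habitat rendered white
    Image.fromarray(img).save(path)
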