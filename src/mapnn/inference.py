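"""Prediction, accuracy metrics, and parametric-bootstrap uncertainty.

Point estimates average many forward passes made with independent random
pair subsets, back-transformed to natural scale.  Accuracy against a
ground-truth map uses the mean relative absolute error (MRAE): the
per-cell |estimate - truth| / truth averaged over evaluated cells, per
channel.  Uncertainty comes from a parametric bootstrap: new datasets
are simulated under the estimated map, re-estimated, and per-cell
empirical quantiles form the confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .model import MapNN, PairSubsetConfig, enumerate_pairs
from .training import TargetTransform

__all__ = [
    "MapEstimate",
    "BootstrapResult",
    "ensemble_predict",
    "mrae",
    "map_correlation",
    "parametric_bootstrap",
    "habitat_geometry",
]


@dataclass
class MapEstimate:
    """Back-transformed point estimate plus its prediction replicates."""

    point: np.ndarray        # (w, w, 2) natural scale, per-cell replicate mean
    replicates: np.ndarray   # (R, w, w, 2)
    mask: np.ndarray | None = None


@dataclass
class BootstrapResult:
    """Per-cell 95% band: empirical 2.5%/97.5% quantiles of re-estimates."""

    lower: np.ndarray
    upper: np.ndarray
    relative_width: np.ndarray   # (upper - lower) / point
    n_redrawn: int = 0           # replicates re-seeded after extinction


def ensemble_predict(model: MapNN, genotypes: np.ndarray, locations: np.ndarray,
                     R: int, transform: TargetTransform,
                     rng: np.random.Generator,
                     pair_config: PairSubsetConfig | None = None,
                     mask: np.ndarray | None = None) -> MapEstimate:
    """Average R forward passes over independent random pair subsets."""
    if R < 1:
        raise ValueError("R must be >= 1")
    c = model.config
    if pair_config is None:
        k = min(c.n * (c.n - 1) // 2, 450)
        pair_config = PairSubsetConfig(k, min(k, 100))
    reps = np.empty((R, c.w, c.w, 2))
    for r in range(R):
        pairs, _ = enumerate_pairs(locations.shape[0], pair_config, rng)
        raw = model.predict_map(genotypes, locations, pairs=pairs)
        reps[r] = transform.invert(raw)
        if mask is not None:
            reps[r][~mask] = np.nan
    point = reps.mean(axis=0)
    return MapEstimate(point, reps, mask)


def _evaluated(true_map, est_map, mask):
    true_map = np.asarray(true_map, dtype=float)
    est_map = np.asarray(est_map, dtype=float)
    if true_map.shape != est_map.shape:
        raise ValueError("map shapes differ")
    sel = np.ones(true_map.shape[:2], dtype=bool) if mask is None else mask.copy()
    # cells with missing realized values (NaN) are excluded, not imputed
    sel &= np.all(np.isfinite(true_map), axis=-1) & np.all(np.isfinite(est_map), axis=-1)
    return true_map, est_map, sel


def mrae(true_map: np.ndarray, est_map: np.ndarray,
         mask: np.ndarray | None = None) -> tuple[float, float]:
    """(MRAE_dispersal, MRAE_density): mean |est - true| / true per channel."""
    true_map, est_map, sel = _evaluated(true_map, est_map, mask)
    if np.any(true_map[sel] <= 0):
        raise ValueError("nonpositive true value on an evaluated cell")
    err = np.abs(est_map[sel] - true_map[sel]) / true_map[sel]
    return float(err[:, 0].mean()), float(err[:, 1].mean())


def map_correlation(true_map: np.ndarray, est_map: np.ndarray,
                    mask: np.ndarray | None = None) -> tuple[float, float]:
    """Squared Pearson correlation per channel over evaluated cells.

    Returns NaN for a channel whose true or estimated values have zero
    variance (the correlation is undefined there).
    """
    true_map, est_map, sel = _evaluated(true_map, est_map, mask)
    if sel.sum() < 3:
        raise ValueError("need at least 3 evaluated cells")
    out = []
    for ch in range(2):
        t, e = true_map[sel][:, ch], est_map[sel][:, ch]
        if np.ptp(t) == 0 or np.ptp(e) == 0:
            out.append(float("nan"))
            continue
        r, _ = stats.pearsonr(t, e)
        out.append(float(r**2))
    return out[0], out[1]


def parametric_bootstrap(point_map: np.ndarray,
                         simulate_and_estimate: Callable[[np.ndarray, np.random.Generator], np.ndarray],
                         B: int, rng: np.random.Generator,
                         mask: np.ndarray | None = None,
                         max_redraws: int = 10) -> BootstrapResult:
    """Simulate B datasets under the estimated map and re-estimate each.

    ``simulate_and_estimate(map, rng)`` runs the full pipeline (simulate,
    sample, genotype, predict) and returns a (w, w, 2) estimate; it may
    raise ``SimulationExtinct``, in which case the replicate is re-drawn
    with a fresh seed (counted in ``n_redrawn``).  Intervals are the
    per-cell empirical 2.5% / 97.5% quantiles (linear interpolation
    between order statistics).
    """
    from .simulate import SimulationExtinct

    reps = []
    redrawn = 0
    while len(reps) < B:
        try:
            reps.append(simulate_and_estimate(point_map, rng))
        except SimulationExtinct:
            redrawn += 1
            if redrawn > max_redraws * B:
                raise
    stack = np.stack(reps)
    lower = np.quantile(stack, 0.025, axis=0)
    upper = np.quantile(stack, 0.975, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (upper - lower) / point_map
    if mask is not None:
        lower[~mask] = np.nan
        upper[~mask] = np.nan
        rel[~mask] = np.nan
    return BootstrapResult(lower, upper, rel, redrawn)


def habitat_geometry(land_area: float, land_fraction: float) -> tuple[float, float]:
    """Square-map geometry from a land area and its fraction of the square.

    Returns (total square area, side width) in the input units; e.g. a
    land mass occupying 21.93% of its bounding square determines the full
    simulation square and its width in km.
    """
    if land_area <= 0 or not 0 < land_fraction <= 1:
        raise ValueError("need land_area > 0 and 0 < land_fraction <= 1")
    total = land_area / land_fraction
    return total, float(np.sqrt(total))
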