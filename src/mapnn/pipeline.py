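"""End-to-end glue: simulation -> sampling -> genotypes -> training datasets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tskit

from .genotypes import (GenotypeConfig, RecapConfig, build_tree_sequence,
                        genome_rate_map, overlay_snps, recapitate, subset_individuals)
from .maps import DemographicMap, MapPrior, draw_map
from .sampling import SamplingScheme, draw_sample
from .simulate import SimParams, SimResult, run_simulation
from .training import MapDataset

__all__ = ["SimulationSource", "simulate_source", "dataset_from_source"]


@dataclass
class SimulationSource:
    """A finished simulation kept resamplable: full population + ancestry.

    ``base_ts`` is simplified to *all* final-cycle individuals (sample j
    owns nodes 2j, 2j+1 in population-array order), so per-draw subsetting
    is cheap.
    """

    dmap: DemographicMap
    params: SimParams
    result: SimResult
    base_ts: tskit.TreeSequence


def simulate_source(dmap: DemographicMap, params: SimParams,
                    rng: np.random.Generator,
                    record_realized: bool = False) -> SimulationSource:
    """Run a simulation with ancestry recording and pre-simplify its tables."""
    res = run_simulation(dmap, params, rng, record_realized=record_realized,
                         record_ancestry=True)
    ts = build_tree_sequence(res.ancestry, params.n_cycles, res.population.gid)
    return SimulationSource(dmap, params, res, ts)


def dataset_from_source(source: SimulationSource, n: int, m_target: int,
                        rng: np.random.Generator,
                        scheme: SamplingScheme | None = None,
                        recap: RecapConfig | None = None,
                        phased: bool = False) -> MapDataset:
    """Draw one training/validation dataset from a simulation.

    Samples individuals per the scheme (uniform by default), completes
    their genealogy by recapitation (single epoch at the final census size
    unless configured otherwise), overlays exactly ``m_target`` SNPs, and
    pairs the genotypes with the simulation-input map as target.
    """
    pop = source.result.population
    w = source.dmap.width
    scheme = scheme or SamplingScheme(mode="uniform", n=n)
    ss = draw_sample(pop, scheme, rng, habitat_width=w)
    sub = subset_individuals(source.base_ts, ss.indices)
    recap = recap or RecapConfig.single(source.result.final_census)
    gm = source.params.genome_map
    rate = gm.rates[0] if len(gm.lengths) == 1 else genome_rate_map(gm.lengths, gm.rates)
    sub = recapitate(sub, recap, rng, recombination_rate=rate)
    gd = overlay_snps(sub, GenotypeConfig(m_target, phased=phased), rng,
                      locations=ss.locations)
    return MapDataset(gd.genotypes, gd.locations, source.dmap.stacked(),
                      source.dmap.habitat_mask)


def random_map(sigma_prior: tuple[float, float], k_prior: tuple[float, float],
               rng: np.random.Generator, width: int,
               max_segments: int = 3) -> DemographicMap:
    """Convenience wrapper: draw a random segmented map from prior ranges."""
    sp = MapPrior(sigma_prior[0], sigma_prior[1], "dispersal")
    kp = MapPrior(k_prior[0], k_prior[1], "density")
    return draw_map(sp, kp, rng, width=width, max_segments=max_segments)
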