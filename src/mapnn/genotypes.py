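"""Genotype synthesis: recapitation, SNP overlay, and VCF interchange.

The forward simulator records parentage and recombination breakpoints for
recent, spatially explicit generations only.  Lineages that have not
coalesced by the start of the forward period are completed backward in
time with a randomly mating coalescent ("recapitation"), after which
mutations are laid down to produce a genotype matrix with an *exact*
number of segregating sites: the mutation rate starts tiny and doubles
until at least the requested number of SNPs segregate, and the final set
is a uniform subsample of those sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
import tskit

from .simulate import AncestryTables

__all__ = [
    "RecapConfig",
    "GenotypeConfig",
    "GenotypeDataset",
    "build_tree_sequence",
    "recapitate",
    "overlay_snps",
    "write_vcf",
    "read_vcf",
    "write_locations_csv",
    "read_locations_csv",
]


@dataclass(frozen=True)
class RecapConfig:
    """Coalescent epochs for recapitation, ordered backward in time.

    ``epochs`` is a list of (Ne, start_generation) with the first entry
    starting at generation 0 (its start value is ignored).  The common
    single-epoch case uses the final-cycle census size as Ne.
    """

    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [t for _, t in self.epochs]
        if any(b <= a for a, b in zip(starts[1:], starts[2:])):
            raise ValueError("epoch start times must increase backward in time")
        if any(ne <= 0 for ne, _ in self.epochs):
            raise ValueError("Ne must be positive")

    @classmethod
    def single(cls, ne: float) -> "RecapConfig":
        return cls(((float(ne), 0.0),))

    def demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop_0", initial_size=self.epochs[0][0])
        for ne, start in self.epochs[1:]:
            dem.add_population_parameters_change(time=start, initial_size=ne)
        return dem


@dataclass(frozen=True)
class GenotypeConfig:
    """SNP-overlay settings: target site count and the starting mutation rate."""

    m_target: int
    phased: bool = False
    mu_start: float = 1e-15

    def __post_init__(self):
        if self.m_target < 1:
            raise ValueError("m_target must be >= 1")


@dataclass
class GenotypeDataset:
    """Minor-allele-count matrix with sample coordinates.

    ``genotypes`` is (n, m) of {0, 1, 2} (or (2n, m) of {0, 1} if phased);
    every column is polymorphic with minor-allele frequency <= 0.5.
    """

    genotypes: np.ndarray
    locations: np.ndarray          # (n, 2) habitat coordinates
    individual_ids: list[str]
    positions: np.ndarray | None = None   # genome coordinates per column
    phased: bool = False
    mu_schedule: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


# ---------------------------------------------------------------------------
# forward-ancestry -> tskit


def build_tree_sequence(ancestry: AncestryTables, n_cycles: int,
                        sample_gids: np.ndarray) -> tskit.TreeSequence:
    """Convert recorded parentage into a simplified tskit tree sequence.

    Node times count cycles back from the end of the run; founders sit one
    cycle older than any recorded birth.  The returned tree sequence is
    simplified so the two nodes of sample individual j are 2j and 2j+1,
    in the order given by ``sample_gids``.
    """
    sample_gids = np.asarray(sample_gids, dtype=np.int64)
    M = ancestry.birth_cycle.size
    tables = tskit.TableCollection(sequence_length=ancestry.sequence_length)
    tables.time_units = "generations"
    tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
    tables.populations.add_row(metadata={"name": "pop_0", "description": ""})
    time = (n_cycles - 1) - ancestry.birth_cycle.astype(float)  # founders: n_cycles
    is_sample = np.zeros(M, dtype=bool)
    is_sample[sample_gids] = True
    node_time = np.repeat(time, 2)
    node_flags = np.where(np.repeat(is_sample, 2), tskit.NODE_IS_SAMPLE, 0).astype(np.uint32)
    ind = tables.individuals
    ind.set_columns(flags=np.zeros(M, dtype=np.uint32))
    tables.nodes.set_columns(
        flags=node_flags, time=node_time,
        population=np.zeros(2 * M, dtype=np.int32),
        individual=np.repeat(np.arange(M, dtype=np.int32), 2))
    tables.edges.set_columns(
        left=ancestry.edge_left, right=ancestry.edge_right,
        parent=ancestry.edge_parent_node.astype(np.int32),
        child=ancestry.edge_child_node.astype(np.int32))
    tables.sort()
    sample_nodes = np.empty(2 * sample_gids.size, dtype=np.int32)
    sample_nodes[0::2] = 2 * sample_gids
    sample_nodes[1::2] = 2 * sample_gids + 1
    tables.simplify(samples=sample_nodes)
    return tables.tree_sequence()


def subset_individuals(ts: tskit.TreeSequence, indices: np.ndarray) -> tskit.TreeSequence:
    """Simplify to a subset of diploid individuals (by sample-order index)."""
    indices = np.asarray(indices, dtype=np.int64)
    nodes = np.empty(2 * indices.size, dtype=np.int32)
    nodes[0::2] = 2 * indices
    nodes[1::2] = 2 * indices + 1
    return ts.simplify(samples=nodes)


# ---------------------------------------------------------------------------
# recapitation and mutations


def recapitate(ts: tskit.TreeSequence, config: RecapConfig,
               rng: np.random.Generator,
               recombination_rate: float | msprime.RateMap = 1e-8) -> tskit.TreeSequence:
    """Complete uncoalesced roots with a randomly mating coalescent.

    After this, every marginal tree has exactly one root.  A tree sequence
    that is already fully coalesced is returned unchanged.
    """
    if all(t.num_roots == 1 for t in ts.trees()):
        return ts
    seed = int(rng.integers(1, 2**31 - 1))
    return msprime.sim_ancestry(
        initial_state=ts, demography=config.demography(),
        recombination_rate=recombination_rate, random_seed=seed)


def genome_rate_map(lengths, rates, boundary_rate: float = np.log(2)) -> msprime.RateMap:
    """Recombination rate map for independent segments.

    Internal 1-bp boundaries carry rate log(2), the standard device for
    approximately unlinked chromosomes in a single coalescent simulation.
    """
    pos = [0.0]
    rate = []
    for i, (L, r) in enumerate(zip(lengths, rates)):
        if i:
            pos.append(pos[-1] + 1.0)
            rate.append(boundary_rate)
        pos.append(pos[-1] + L - (1.0 if i else 0.0))
        rate.append(r)
    return msprime.RateMap(position=pos, rate=rate)


def _minor_allele_recode(derived: np.ndarray, phased: bool) -> np.ndarray:
    """Recode derived-allele counts so columns count the minor allele.

    Ties at frequency exactly 1/2 count the lexicographically first allele
    label ("0", the ancestral state), which makes the coding deterministic.
    """
    n_copies = derived.shape[0] * (1 if phased else 2)
    total = derived.sum(axis=0, dtype=np.int64)
    flip = 2 * total >= n_copies  # ties flip to the ancestral "0" label
    out = derived.copy()
    top = 1 if phased else 2
    out[:, flip] = top - out[:, flip]
    return out


def overlay_snps(ts: tskit.TreeSequence, config: GenotypeConfig,
                 rng: np.random.Generator,
                 locations: np.ndarray | None = None,
                 individual_ids: list[str] | None = None) -> GenotypeDataset:
    """Simulate mutations until exactly ``m_target`` SNPs segregate.

    Mutations are added under an infinite-sites model at rate
    mu_start * 2^k, doubling k until the sample carries at least m_target
    segregating sites; a uniform subsample of exactly m_target sites is
    retained and recoded to minor-allele counts.
    """
    if any(t.num_roots != 1 for t in ts.trees()):
        raise ValueError("tree sequence has uncoalesced roots; recapitate first")
    mu = config.mu_start
    added = 0.0
    schedule = []
    current = ts
    while True:
        schedule.append(mu)
        seed = int(rng.integers(1, 2**31 - 1))
        current = msprime.sim_mutations(
            current, rate=mu - added, random_seed=seed, keep=True,
            discrete_genome=False, model=msprime.BinaryMutationModel())
        added = mu
        if current.num_sites >= config.m_target:
            break
        mu *= 2.0
    keep = np.sort(rng.choice(current.num_sites, size=config.m_target, replace=False))
    drop = np.setdiff1d(np.arange(current.num_sites), keep)
    current = current.delete_sites(drop)
    hap = current.genotype_matrix().T.astype(np.int16)   # (2n, m) of 0/1
    assert hap.max(initial=0) <= 1, "infinite-sites assumption violated"
    positions = current.tables.sites.position.copy()
    if config.phased:
        geno = _minor_allele_recode(hap, phased=True)
    else:
        geno = _minor_allele_recode(hap[0::2] + hap[1::2], phased=False)
    n = current.num_samples // 2
    if locations is None:
        locations = np.zeros((n, 2))
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(n)]
    return GenotypeDataset(geno, np.asarray(locations, dtype=float),
                           list(individual_ids), positions, config.phased, schedule)


# ---------------------------------------------------------------------------
# VCF + locations interchange


def _integer_positions(positions: np.ndarray, length: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Discretize continuous positions to distinct 1-based integers."""
    pos = np.floor(positions).astype(np.int64) + 1
    seen = set()
    for i in range(pos.size):
        while pos[i] in seen:
            pos[i] = int(rng.integers(1, max(int(length), pos.size + 1)))
        seen.add(int(pos[i]))
    order = np.argsort(pos, kind="stable")
    return pos, order


def write_vcf(dataset: GenotypeDataset, path: str | Path,
              contig: str = "1", contig_length: float = 1e8,
              rng: np.random.Generator | None = None) -> None:
    """Write biallelic SNPs as an uncompressed VCF 4.2 with GT fields."""
    rng = rng or np.random.default_rng(0)
    m = dataset.m
    if dataset.positions is not None:
        pos, order = _integer_positions(dataset.positions, contig_length, rng)
    else:
        pos, order = np.arange(1, m + 1), np.arange(m)
    geno = dataset.genotypes.copy()
    # At exact 50/50 columns the stored counts refer to the lexicographically
    # first allele (written as REF "A"); emit ALT counts so a re-read flips
    # back to the identical matrix.
    n_copies = geno.shape[0] * (1 if dataset.phased else 2)
    tie = 2 * geno.sum(axis=0, dtype=np.int64) == n_copies
    top = 1 if dataset.phased else 2
    geno[:, tie] = top - geno[:, tie]
    if dataset.phased:
        a = geno[0::2], geno[1::2]
        sep = "|"
    else:
        a = (np.maximum(geno - 1, 0), np.minimum(geno, 1))
        sep = "/"
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={int(contig_length)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dataset.individual_ids),
    ]
    for j in order:
        gts = "\t".join(f"{a[0][i, j]}{sep}{a[1][i, j]}" for i in range(dataset.n))
        lines.append(f"{contig}\t{pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, locations_csv: str | Path,
             phased: bool = False) -> tuple[GenotypeDataset, dict]:
    """Read biallelic SNPs plus a sample-coordinates table.

    Sites with any missing genotype, indels, and non-biallelic records are
    dropped (counts reported in the returned dict).  Sample names must
    match the locations table exactly; offenders are listed otherwise.
    """
    from cyvcf2 import VCF

    loc = read_locations_csv(locations_csv)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_in_csv = [s for s in samples if s not in loc.index]
    extra_in_csv = [s for s in loc.index if s not in samples]
    if missing_in_csv or extra_in_csv:
        raise ValueError(
            f"sample-name mismatch: VCF-only={missing_in_csv}, table-only={extra_in_csv}")
    cols, positions = [], []
    dropped = {"non_biallelic": 0, "missing": 0, "indel": 0}
    for var in vcf:
        if len(var.ALT) != 1:
            dropped["non_biallelic"] += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            dropped["indel"] += 1
            continue
        g = np.array([gt[:2] for gt in var.genotypes], dtype=np.int16)
        if (g < 0).any():
            dropped["missing"] += 1
            continue
        cols.append(g)
        positions.append(var.POS)
    if not cols:
        raise ValueError("no usable biallelic, fully called SNPs in VCF")
    hap = np.stack([c.reshape(-1) for c in cols], axis=1)  # (2n, m)
    if phased:
        geno = _minor_allele_recode(hap, phased=True)
    else:
        geno = _minor_allele_recode(hap[0::2] + hap[1::2], phased=False)
    coords = loc.loc[samples, ["x", "y"]].to_numpy(dtype=float)
    ds = GenotypeDataset(geno, coords, samples, np.asarray(positions, dtype=float),
                         phased)
    return ds, dropped


def write_locations_csv(dataset: GenotypeDataset, path: str | Path) -> None:
    pd.DataFrame({"individual_id": dataset.individual_ids,
                  "x": dataset.locations[:, 0],
                  "y": dataset.locations[:, 1]}).to_csv(path, index=False)


def read_locations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"individual_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"locations table needs columns {sorted(required)}")
    return df.set_index("individual_id")
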