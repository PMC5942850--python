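"""Synthetic serial-transfer evolution experiment generator.

A haplotype-based Wright-Fisher simulator for asexual populations under
daily growth-dilution cycles, plus samplers for pooled sequencing reads,
fluctuation-assay mutant counts, logistic growth curves and endpoint plate
readings.  Every downstream analysis module can therefore be exercised on
data with known ground truth.

Cycle structure: the population starts each day at the bottleneck size
``round(n_max / dilution)``, doubles for ``floor(log2(dilution))``
selection-weighted generations, is censused at ``n_max`` (the fractional
final generation), and is then bottlenecked by multinomial sampling.
Mutation numbers per generation are Poisson with genome-uniform placement
under infinite sites (collisions re-drawn); linkage is exact because
genomes are whole haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype import GrowthCurve

__all__ = [
    "DFE",
    "MutatorLocus",
    "SimulationConfig",
    "Mutation",
    "HaplotypePopulation",
    "Snapshot",
    "ExtinctionError",
    "simulate_replicate",
    "sample_reads",
    "simulate_fluctuation",
    "simulate_growth_curve",
    "simulate_plate",
    "replicate_seeds",
]

_BASES = np.array(["A", "C", "G", "T"])
_EFFECT_CLASSES = ("synonymous", "nonsynonymous", "nonsense")
_EFFECT_PROBS = (0.25, 0.70, 0.05)


class ExtinctionError(RuntimeError):
    """Raised when a simulated population loses every cell."""


@dataclass
class DFE:
    """Point-mass distribution of fitness effects per mutation class."""

    fraction_beneficial: float = 0.0
    beneficial_effect: float = 0.03
    fraction_deleterious: float = 0.0
    deleterious_effect: float = 0.03

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_beneficial <= 1:
            raise ValueError("fraction_beneficial must be in [0, 1]")
        if not 0 <= self.fraction_deleterious <= 1:
            raise ValueError("fraction_deleterious must be in [0, 1]")
        if self.fraction_beneficial + self.fraction_deleterious > 1:
            raise ValueError("beneficial + deleterious fractions exceed 1")
        if self.fraction_beneficial > 0 and self.beneficial_effect <= 0:
            raise ValueError("beneficial_effect must be > 0")
        if self.fraction_deleterious > 0 and self.deleterious_effect <= 0:
            raise ValueError("deleterious_effect must be > 0")


@dataclass
class MutatorLocus:
    """Optional locus whose mutation multiplies the carrier's genomic rate."""

    position: int
    rate_multiplier: float


@dataclass
class SimulationConfig:
    genome_length: int
    U: float
    n_max: int
    dilution: float
    days: int
    replicates: int = 1
    seed: int = 0
    dfe: DFE = field(default_factory=DFE)
    gene_table: pd.DataFrame | None = None
    seq_depth: float = 200.0
    detection_threshold: float = 0.05
    mutator_locus: MutatorLocus | None = None
    beneficial_gene: str | None = None

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.U < 0:
            raise ValueError("U must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")
        if self.n_max < self.dilution:
            raise ValueError("n_max must be >= dilution (bottleneck >= 1 cell)")
        if not 0 <= self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in [0, 1)")
        if self.beneficial_gene is not None:
            if self.gene_table is None or (
                self.beneficial_gene not in set(self.gene_table["gene_id"])
            ):
                raise ValueError(
                    f"beneficial_gene {self.beneficial_gene!r} not in gene table"
                )

    @property
    def generations_per_cycle(self) -> float:
        return math.log2(self.dilution) if self.dilution > 1 else 0.0

    @property
    def complete_doublings(self) -> int:
        return math.floor(self.generations_per_cycle)

    @property
    def bottleneck_size(self) -> int:
        return round(self.n_max / self.dilution)


@dataclass(frozen=True)
class Mutation:
    position: int  # 1-based
    ref_base: str
    derived_base: str
    effect_class: str
    s: float
    is_mutator: bool = False


@dataclass
class HaplotypePopulation:
    """Counts of whole-genome haplotypes (tuples of carried mutations)."""

    haplotypes: list[tuple[Mutation, ...]]
    counts: np.ndarray
    fitness: np.ndarray
    mutation_rates: np.ndarray

    @property
    def size(self) -> int:
        return int(self.counts.sum())

    def mean_fitness(self) -> float:
        return float(np.average(self.fitness, weights=self.counts))

    def allele_frequencies(self) -> pd.DataFrame:
        """True derived-allele frequencies per segregating site."""
        total = self.size
        acc: dict[tuple[int, str], list] = {}
        for hap, count in zip(self.haplotypes, self.counts):
            if count == 0:
                continue
            for mut in hap:
                key = (mut.position, mut.derived_base)
                if key in acc:
                    acc[key][0] += int(count)
                else:
                    acc[key] = [int(count), mut]
        rows = [
            {
                "position": mut.position,
                "ref_base": mut.ref_base,
                "derived_base": mut.derived_base,
                "effect_class": mut.effect_class,
                "frequency": n / total,
                "s": mut.s,
            }
            for n, mut in acc.values()
        ]
        df = pd.DataFrame(
            rows,
            columns=["position", "ref_base", "derived_base", "effect_class", "frequency", "s"],
        )
        return df.sort_values(["position", "derived_base"]).reset_index(drop=True)


@dataclass
class Snapshot:
    cycle: int
    generation: int
    population: HaplotypePopulation
    mean_fitness: float


def replicate_seeds(seed: int, replicates: int) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate child seeds from one root seed."""
    return np.random.SeedSequence(seed).spawn(replicates)


class _GeneIndex:
    """Position -> gene_id lookup over 1-based inclusive intervals."""

    def __init__(self, gene_table: pd.DataFrame | None):
        if gene_table is None or not len(gene_table):
            self.starts = np.array([], dtype=int)
            self.ends = np.array([], dtype=int)
            self.ids: list[str] = []
            self._max_len = 0
            return
        tab = gene_table.sort_values("start")
        self.starts = tab["start"].to_numpy(dtype=int)
        self.ends = tab["end"].to_numpy(dtype=int)
        self.ids = tab["gene_id"].astype(str).tolist()
        self._max_len = int((self.ends - self.starts).max()) + 1

    def lookup(self, position: int) -> str:
        i = int(np.searchsorted(self.starts, position, side="right")) - 1
        # overlapping genes allowed: scan left until starts fall out of reach
        while i >= 0 and self.starts[i] > position - self._max_len:
            if self.ends[i] >= position:
                return self.ids[i]
            i -= 1
        return "intergenic"


def _draw_mutation(
    config: SimulationConfig,
    rng: np.random.Generator,
    used_positions: set[int],
    gene_index: _GeneIndex,
    pop: "_Population",
) -> Mutation:
    # infinite sites: re-draw on collision with any position already used.
    # When cumulative events approach genome saturation, recycle positions
    # of extinct lineages (live polymorphisms stay unique per position).
    for _ in range(3):
        for _ in range(200):
            position = int(rng.integers(1, config.genome_length + 1))
            if position not in used_positions:
                break
        else:
            used_positions.clear()
            used_positions.update(pop.live_positions())
            continue
        break
    else:
        raise RuntimeError(
            "genome saturated: no free positions left for new mutations"
        )
    used_positions.add(position)
    ref, derived = rng.choice(_BASES, size=2, replace=False)
    gene = gene_index.lookup(position)
    effect_class = (
        "intergenic" if gene == "intergenic" else str(rng.choice(_EFFECT_CLASSES, p=_EFFECT_PROBS))
    )
    is_mutator = (
        config.mutator_locus is not None and position == config.mutator_locus.position
    )
    if config.beneficial_gene is not None:
        # planted-gene mode: beneficial effects occur only inside the target
        if gene == config.beneficial_gene:
            s = config.dfe.beneficial_effect
        elif rng.random() < config.dfe.fraction_deleterious:
            s = -config.dfe.deleterious_effect
        else:
            s = 0.0
    else:
        u = rng.random()
        if u < config.dfe.fraction_beneficial:
            s = config.dfe.beneficial_effect
        elif u < config.dfe.fraction_beneficial + config.dfe.fraction_deleterious:
            s = -config.dfe.deleterious_effect
        else:
            s = 0.0
    return Mutation(
        position=position, ref_base=str(ref), derived_base=str(derived),
        effect_class=effect_class, s=s, is_mutator=is_mutator,
    )


class _Population:
    """Mutable haplotype bookkeeping used inside the generation loop."""

    def __init__(self, n0: int, base_rate: float):
        self.haps: list[tuple[Mutation, ...]] = [()]
        self.counts = np.array([n0], dtype=np.int64)
        self.fitness = np.array([1.0])
        self.rates = np.array([base_rate])
        self.index: dict[tuple[Mutation, ...], int] = {(): 0}

    def prune(self) -> None:
        keep = self.counts > 0
        if keep.all():
            return
        self.haps = [h for h, k in zip(self.haps, keep) if k]
        self.counts = self.counts[keep]
        self.fitness = self.fitness[keep]
        self.rates = self.rates[keep]
        self.index = {h: i for i, h in enumerate(self.haps)}

    def add(self, hap: tuple[Mutation, ...], fitness: float, rate: float) -> int:
        i = self.index.get(hap)
        if i is None:
            self.haps.append(hap)
            self.counts = np.append(self.counts, 0)
            self.fitness = np.append(self.fitness, fitness)
            self.rates = np.append(self.rates, rate)
            i = len(self.haps) - 1
            self.index[hap] = i
        return i

    def live_positions(self) -> set[int]:
        out: set[int] = set()
        for hap, count in zip(self.haps, self.counts):
            if count > 0:
                out.update(m.position for m in hap)
        return out

    def freeze(self) -> HaplotypePopulation:
        return HaplotypePopulation(
            haplotypes=list(self.haps),
            counts=self.counts.copy(),
            fitness=self.fitness.copy(),
            mutation_rates=self.rates.copy(),
        )


def _resample(pop: _Population, new_size: int, rng: np.random.Generator) -> None:
    weights = pop.counts * pop.fitness
    total = weights.sum()
    if total <= 0:
        raise ExtinctionError("population went extinct (no viable cells)")
    pop.counts = rng.multinomial(new_size, weights / total).astype(np.int64)
    pop.prune()


def _mutate(
    pop: _Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    used_positions: set[int],
    gene_index: _GeneIndex,
) -> None:
    n_haps = len(pop.haps)
    events = rng.poisson(pop.rates * pop.counts)
    for i in range(n_haps):
        k = int(min(events[i], pop.counts[i]))
        for _ in range(k):
            mut = _draw_mutation(config, rng, used_positions, gene_index, pop)
            parent = pop.haps[i]
            child = tuple(sorted(parent + (mut,), key=lambda m: (m.position, m.derived_base)))
            fit = pop.fitness[i] * (1.0 + mut.s)
            rate = pop.rates[i]
            if mut.is_mutator:
                rate *= config.mutator_locus.rate_multiplier
            j = pop.add(child, fit, rate)
            pop.counts[i] -= 1
            pop.counts[j] += 1
    pop.prune()


def simulate_replicate(
    config: SimulationConfig,
    replicate_seed,
    snapshot_cycles: list[int] | None = None,
) -> list[Snapshot]:
    """Run one replicate population for ``config.days`` growth-dilution cycles.

    Snapshots are taken at stationary phase (census size ``n_max``) of each
    cycle listed in ``snapshot_cycles`` (default: the final cycle only).
    Identical ``(config, replicate_seed)`` gives bit-identical trajectories.
    """
    rng = np.random.default_rng(replicate_seed)
    if snapshot_cycles is None:
        snapshot_cycles = [config.days]
    wanted = set(snapshot_cycles)
    gene_index = _GeneIndex(config.gene_table)
    used_positions: set[int] = set()
    pop = _Population(config.bottleneck_size, config.U)
    snapshots: list[Snapshot] = []
    k = config.complete_doublings
    generation = 0
    for cycle in range(1, config.days + 1):
        n0 = pop.counts.sum()
        if n0 <= 0:
            raise ExtinctionError(f"population extinct entering cycle {cycle}")
        for g in range(1, k + 1):
            target = min(int(config.bottleneck_size * 2**g), config.n_max)
            _resample(pop, target, rng)
            _mutate(pop, config, rng, used_positions, gene_index)
            generation += 1
        if config.n_max > config.bottleneck_size * 2**k or config.dilution == 1:
            _resample(pop, config.n_max, rng)  # fractional final generation
            _mutate(pop, config, rng, used_positions, gene_index)
            generation += 1
        if cycle in wanted:
            frozen = pop.freeze()
            snapshots.append(
                Snapshot(
                    cycle=cycle,
                    generation=generation,
                    population=frozen,
                    mean_fitness=frozen.mean_fitness(),
                )
            )
        if config.dilution > 1:
            _resample(pop, config.bottleneck_size, rng)
    return snapshots


def sample_reads(
    true_freqs: pd.DataFrame,
    depth: float,
    detection_threshold: float,
    seed,
    population_id: str = "pop",
    generation: int = 0,
    gene_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Pooled-sequencing sampler: per site, depth ~ Poisson(mean depth) and
    derived reads ~ Binomial(depth, true frequency).

    Sites with reported frequency below ``detection_threshold`` (including
    zero-frequency sites) are omitted; zero-depth sites are omitted and
    tallied in the coverage report.  Returns (variant table, report).
    """
    rng = np.random.default_rng(seed)
    true_freqs = true_freqs.copy()
    for col, default in (
        ("ref_base", "A"),
        ("derived_base", "C"),
        ("effect_class", "intergenic"),
    ):
        if col not in true_freqs.columns:
            true_freqs[col] = default
    freqs = true_freqs["frequency"].to_numpy(dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("true frequencies must be in [0, 1]")
    n = len(true_freqs)
    depths = rng.poisson(depth, size=n)
    derived_reads = rng.binomial(depths, freqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        reported = np.where(depths > 0, derived_reads / np.maximum(depths, 1), 0.0)
    zero_depth = depths == 0
    detected = (~zero_depth) & (reported >= detection_threshold) & (reported > 0)
    gene_index = _GeneIndex(gene_table)
    rows = true_freqs.loc[detected].copy()
    rows["frequency"] = reported[detected]
    rows["depth"] = depths[detected]
    majority_derived = reported[detected] > 0.5
    rows["majority_reads"] = np.where(
        majority_derived,
        derived_reads[detected],
        depths[detected] - derived_reads[detected],
    )
    rows["population_id"] = population_id
    rows["generation"] = generation
    if "gene_id" not in rows.columns:
        rows["gene_id"] = [gene_index.lookup(p) for p in rows["position"]]
    table = rows[
        [
            "population_id", "generation", "position", "ref_base", "derived_base",
            "frequency", "depth", "majority_reads", "gene_id", "effect_class",
        ]
    ].reset_index(drop=True)
    report = {
        "sites_in": int(n),
        "zero_depth_sites": int(zero_depth.sum()),
        "below_threshold": int((~detected & ~zero_depth).sum()),
        "reported_sites": int(detected.sum()),
    }
    return table, report


def simulate_fluctuation(
    mu: float, n_final: float, cultures: int, seed
) -> pd.DataFrame:
    """Luria-Delbrueck mutant counts for parallel cultures.

    Mutation events per culture are Poisson with mean ``m = mu * n_final``;
    each event founds a clone whose final size is drawn from the
    Lea-Coulson size law ``P(size = k) = 1 / (k (k + 1))`` (sampled exactly
    as ``floor(1/u)``, u uniform), capped at the culture size.  This is the
    stochastic representation matching the likelihood in
    :mod:`mutcloud.fluctuation` exactly.
    """
    if mu < 0 or n_final <= 0:
        raise ValueError("need mu >= 0 and n_final > 0")
    if cultures < 1:
        raise ValueError("cultures must be >= 1")
    m = mu * n_final
    if not math.isfinite(m):
        raise ValueError("mu * n_final must be finite")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(m, size=cultures)
    counts = np.zeros(cultures, dtype=np.int64)
    for i, k in enumerate(n_events):
        if k == 0:
            continue
        clone_sizes = np.minimum(
            np.floor(1.0 / rng.random(k)).astype(np.int64), int(n_final)
        )
        counts[i] = clone_sizes.sum()
    return pd.DataFrame(
        {
            "culture_id": [f"c{i + 1}" for i in range(cultures)],
            "mutant_count": counts,
            "n_final": float(n_final),
        }
    )


def simulate_growth_curve(
    r: float,
    K: float,
    n0: float,
    times,
    noise_sd: float = 0.0,
    seed=None,
    sample_id: str = "",
) -> GrowthCurve:
    """Logistic growth readings with i.i.d. Gaussian noise."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if not K > n0 > 0:
        raise ValueError("need K > n0 > 0")
    times = np.asarray(times, dtype=float)
    readings = K / (1.0 + ((K - n0) / n0) * np.exp(-r * times))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        readings = readings + rng.normal(0.0, noise_sd, size=times.shape)
    return GrowthCurve(times=times, readings=readings, sample_id=sample_id)


def simulate_plate(
    effects: pd.DataFrame,
    noise_sd: float = 0.0,
    baseline: float = 0.08,
    seed=None,
) -> pd.DataFrame:
    """Endpoint plate readings from planted growth effects.

    ``effects`` has columns sample_id, compound, well, effect (the true
    24-hour absorbance gain).  Output is long format with one 10-minute
    (near-baseline) and one 24-hour (baseline + effect) reading per record,
    both with Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    n = len(effects)
    rows = []
    noise10 = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    noise24 = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for i, rec in enumerate(effects.itertuples(index=False)):
        rows.append(
            (rec.sample_id, rec.compound, rec.well, "10m", baseline + noise10[i])
        )
        rows.append(
            (rec.sample_id, rec.compound, rec.well, "24h", baseline + rec.effect + noise24[i])
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "compound", "well", "time_label", "od600"]
    )
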