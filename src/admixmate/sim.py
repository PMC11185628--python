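"""Wright-Fisher-style forward simulation of two-way admixture with biased mating.

A census of N diploid, hermaphroditic individuals is founded by a single
admixture pulse (a fraction ``m`` from source population 1, the rest from
source 2) and stepped through discrete, non-overlapping generations. Each
generation consists of exactly N mating events: parent 1 is sampled
uniformly with replacement, parent 2 proportional to the mate-choice weight
psi (selfing prohibited), and each event produces one child from two
recombinant gametes. Children inherit the social group of parent 1 —
group membership is transmitted culturally, not genetically.

Optionally, a fraction of each new generation is replaced by fresh
unadmixed migrants (half from each source) who join the mating pool from
the following generation onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    DEFAULT_RECOMB_RATE,
    GenomeMap,
    Individual,
    TractSet,
    collect_tract_lengths,
    meiosis,
)
from .mate_choice import KINDS, MateChoiceModel, sample_mate_index

__all__ = [
    "SimConfig",
    "GenerationStats",
    "SimulationResult",
    "init_population",
    "step_generation",
    "run_simulation",
    "run_replicates",
]

PAIR_COLUMNS = ("t", "x_i", "x_j", "s_i", "s_j", "migrant_i", "migrant_j")

_GROUPS = np.array(["A", "B"])


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation scenario.

    Parameters
    ----------
    n : int
        Census population size per generation (even, >= 2).
    generations : int
        Number of generations to simulate post-admixture.
    kind : str
        Mate-choice kernel ("random", "stationary", "increasing", "broad",
        "social").
    alpha : float
        Mate-choice strength (endogamy:exogamy ratio at founding).
    m : float
        Founding fraction contributed by source population 1.
    migration_rate : float
        Fraction of each generation replaced by fresh unadmixed migrants
        (0 for a single admixture pulse; the continuous-migration scenario
        uses 0.01).
    chrom_lengths : sequence of int, optional
        Chromosome lengths in bp; defaults to the 22 rescaled human
        autosomes (2.88 Gb total).
    recomb_rate : float
        Uniform per-bp recombination rate.
    seed : int
        Base seed; combined with the replicate index for independent runs.
    n_replicates : int
        Number of replicate simulations for ``run_replicates``.
    snapshot_generations : sequence of int
        Generations at which tract-length tables are retained.
    keep_population : bool
        Retain the final generation's individuals (needed for BED output).
    """

    n: int = 10_000
    generations: int = 50
    kind: str = "random"
    alpha: float = 1.0
    m: float = 0.5
    migration_rate: float = 0.0
    chrom_lengths: Sequence[int] | None = None
    recomb_rate: float = DEFAULT_RECOMB_RATE
    seed: int = 0
    n_replicates: int = 1
    snapshot_generations: Sequence[int] = (1, 10, 20, 50)
    keep_population: bool = False

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2:
            raise ValueError("n must be an even integer >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.kind not in KINDS:
            raise ValueError(f"unknown mate-choice kind {self.kind!r}")
        if not 0 < self.m < 1:
            raise ValueError("m must be in (0, 1)")
        if not 0 <= self.migration_rate < 1:
            raise ValueError("migration_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        # normalize sequence fields so value equality is well-defined
        object.__setattr__(
            self, "snapshot_generations", tuple(int(t) for t in self.snapshot_generations)
        )
        if self.chrom_lengths is not None:
            object.__setattr__(
                self, "chrom_lengths", tuple(int(v) for v in self.chrom_lengths)
            )

    def genome_map(self) -> GenomeMap:
        if self.chrom_lengths is None:
            return GenomeMap(recomb_rate=self.recomb_rate)
        return GenomeMap(
            chrom_lengths=np.asarray(self.chrom_lengths, dtype=np.int64),
            recomb_rate=self.recomb_rate,
        )

    def model(self, var0: float = 0.25) -> MateChoiceModel:
        return MateChoiceModel(kind=self.kind, alpha=self.alpha, var0=var0)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "generations": self.generations,
            "kind": self.kind,
            "alpha": self.alpha,
            "m": self.m,
            "migration_rate": self.migration_rate,
            "recomb_rate": self.recomb_rate,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "snapshot_generations": list(self.snapshot_generations),
            "keep_population": self.keep_population,
        }
        if self.chrom_lengths is not None:
            d["chrom_lengths"] = [int(v) for v in self.chrom_lengths]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class GenerationStats:
    """Per-generation summary row.

    ``r`` is the Pearson correlation of global ancestry proportion over the
    mating pairs that produced generation ``t``; ``sigma2`` the population
    variance of x among generation-``t`` individuals.
    """

    t: int
    r: float
    r_symmetrized: float
    sigma2: float
    admixed_fraction: float
    migrant_mating_fraction: float
    group_assoc: float
    perm_p: float = float("nan")


@dataclass
class SimulationResult:
    """Output of one replicate: summary table, mating records, tract tables."""

    config: SimConfig
    replicate: int
    seed: int
    summary: pd.DataFrame
    pairs: pd.DataFrame
    tract_lengths: dict[int, pd.DataFrame] = field(default_factory=dict)
    final_population: list[Individual] | None = None

    def pairs_at(self, t: int) -> pd.DataFrame:
        return self.pairs[self.pairs["t"] == t]

    def r_at(self, t: int) -> float:
        row = self.summary[self.summary["t"] == t]
        if row.empty:
            raise KeyError(f"no summary row for generation {t}")
        return float(row["r"].iloc[0])


def _round_half_even(value: float) -> int:
    return int(round(value))


def init_population(config: SimConfig, gmap: GenomeMap | None = None) -> list[Individual]:
    """Found the admixed population: round(m*N) pure source-1 individuals
    (x=1, group A) and the remainder pure source-2 (x=0, group B)."""
    gmap = gmap or config.genome_map()
    n1 = _round_half_even(config.m * config.n)
    pop = [Individual.founder(1, gmap, id=i) for i in range(n1)]
    pop += [Individual.founder(2, gmap, id=i) for i in range(n1, config.n)]
    return pop


def _pop_arrays(population: Sequence[Individual]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([ind.x for ind in population], dtype=float)
    s_code = np.array([0 if ind.group == "A" else 1 for ind in population], dtype=np.uint8)
    migrant = np.array([ind.is_migrant for ind in population], dtype=bool)
    return x, s_code, migrant


def step_generation(
    population: Sequence[Individual],
    model: MateChoiceModel,
    config: SimConfig,
    rng: np.random.Generator,
    t: int = 0,
    next_id: int = 0,
    gmap: GenomeMap | None = None,
) -> tuple[list[Individual], pd.DataFrame]:
    """Advance one generation: N mating events, then optional migrant influx.

    Returns the new population (size N) and the mating-record table for the
    N events. For the increasing kernel the ancestry variance sigma_x^2 is
    computed once over the parental generation, before any mating event.
    Migrants replace randomly chosen newborns, so they appear in the
    population but not in this generation's mating records; they mate from
    the next generation onward.
    """
    gmap = gmap or config.genome_map()
    n = config.n
    x, s_code, migrant = _pop_arrays(population)
    var_t = float(np.var(x)) if model.needs_variance else 0.0
    two_l = 2 * gmap.total_length

    p1 = rng.integers(0, n, size=n)
    p2 = np.empty(n, dtype=np.int64)
    children: list[Individual] = []
    for k in range(n):
        i = int(p1[k])
        j = sample_mate_index(i, x, s_code, model, rng, var_t)
        p2[k] = j
        g1 = meiosis(population[i], gmap, rng)
        g2 = meiosis(population[j], gmap, rng)
        bp1 = g1.source_bp(1) + g2.source_bp(1)
        children.append(
            Individual(
                hap1=g1,
                hap2=g2,
                x=bp1 / two_l,
                group=population[i].group,
                is_migrant=False,
                id=next_id + k,
            )
        )

    ids = np.array([ind.id for ind in population], dtype=np.int64)
    records = pd.DataFrame(
        {
            "t": np.full(n, t, dtype=np.int64),
            "id_i": ids[p1],
            "id_j": ids[p2],
            "x_i": x[p1],
            "x_j": x[p2],
            "s_i": _GROUPS[s_code[p1]],
            "s_j": _GROUPS[s_code[p2]],
            "migrant_i": migrant[p1],
            "migrant_j": migrant[p2],
        }
    )

    n_mig = _round_half_even(config.migration_rate * n)
    if n_mig:
        n_mig1 = _round_half_even(n_mig / 2)
        slots = rng.choice(n, size=n_mig, replace=False)
        for idx, slot in enumerate(slots):
            source = 1 if idx < n_mig1 else 2
            children[slot] = Individual.founder(
                source, gmap, id=next_id + n + idx, is_migrant=True
            )
    return children, records


def _generation_stats(
    t: int, population: Sequence[Individual], records: pd.DataFrame
) -> GenerationStats:
    from . import stats as _stats  # local import to avoid a cycle

    x = np.array([ind.x for ind in population], dtype=float)
    return GenerationStats(
        t=t,
        r=_stats.mate_correlation(records),
        r_symmetrized=_stats.mate_correlation(records, symmetrize=True),
        sigma2=float(np.var(x)),
        admixed_fraction=float(np.mean((x > 0) & (x < 1))),
        migrant_mating_fraction=_stats.migrant_mating_fraction(records),
        group_assoc=_stats.group_ancestry_association(population),
    )


def run_simulation(
    config: SimConfig,
    replicate: int = 0,
    seed: int | None = None,
) -> SimulationResult:
    """Run one replicate for ``config.generations`` generations.

    Fully reproducible: the random stream is seeded from
    ``(seed, replicate)``. Tract-length tables are retained at
    ``config.snapshot_generations`` (intersected with the simulated range).
    """
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, replicate])
    gmap = config.genome_map()

    population = init_population(config, gmap)
    x0 = np.array([ind.x for ind in population], dtype=float)
    model = config.model(var0=float(np.var(x0)))

    snapshots = {int(t) for t in config.snapshot_generations}
    rows: list[GenerationStats] = []
    all_records: list[pd.DataFrame] = []
    tract_tables: dict[int, pd.DataFrame] = {}
    next_id = config.n

    for t in range(1, config.generations + 1):
        population, records = step_generation(
            population, model, config, rng, t=t, next_id=next_id, gmap=gmap
        )
        next_id += config.n + _round_half_even(config.migration_rate * config.n)
        rows.append(_generation_stats(t, population, records))
        all_records.append(records)
        if t in snapshots:
            lengths, censored = collect_tract_lengths(
                population, source="both", gmap=gmap, return_censored=True
            )
            sources = np.concatenate(
                [hap.sources for ind in population for hap in (ind.hap1, ind.hap2)]
            )
            tract_tables[t] = pd.DataFrame(
                {"length_bp": lengths, "source": sources, "censored": censored}
            )

    summary = pd.DataFrame([vars(row) for row in rows])
    return SimulationResult(
        config=config,
        replicate=replicate,
        seed=base_seed,
        summary=summary,
        pairs=pd.concat(all_records, ignore_index=True),
        tract_lengths=tract_tables,
        final_population=list(population) if config.keep_population else None,
    )


def run_replicates(config: SimConfig, seed: int | None = None) -> list[SimulationResult]:
    """Run ``config.n_replicates`` independent replicates sequentially."""
    return [
        run_simulation(config, replicate=k, seed=seed)
        for k in range(config.n_replicates)
    ]
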