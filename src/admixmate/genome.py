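"""Diploid genome as source-labeled ancestry tracts, and meiosis.

Each haplotype of an individual descends from one of two source populations
at every position; a *local-ancestry tract* is a maximal contiguous interval
inherited from a single source. The genome is a set of independently
segregating chromosomes with a uniform per-bp recombination rate, so tract
boundaries arise only from crossovers between opposite-source segments and
from chromosome ends.

Coordinates are 0-based, half-open ``[start, end)``, in base pairs.
Internally a haplotype is stored genome-wide as two flat arrays (tract end
coordinates on a concatenated chromosome axis, and tract sources), which
keeps meiosis a handful of vectorized operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "HUMAN_AUTOSOME_LENGTHS",
    "GenomeMap",
    "TractSet",
    "Individual",
    "draw_crossovers",
    "meiosis",
    "global_ancestry",
    "collect_tract_lengths",
]

# GRCh38 autosome lengths (chr1..chr22, bp), used only as relative sizes.
_GRCH38_AUTOSOMES = np.array(
    [
        248956422, 242193529, 198295559, 190214555, 181538259, 170805979,
        159345973, 145138636, 138394717, 133797422, 135086622, 133275309,
        114364328, 107043718, 101991189, 90338345, 83257441, 80373285,
        58617616, 64444167, 46709983, 50818468,
    ],
    dtype=np.int64,
)

DEFAULT_GENOME_SIZE = 2_880_000_000
DEFAULT_RECOMB_RATE = 1e-8


def _rescaled_autosomes(total: int = DEFAULT_GENOME_SIZE) -> np.ndarray:
    """22 human autosome lengths linearly rescaled to sum exactly to `total`."""
    scaled = np.floor(_GRCH38_AUTOSOMES * (total / _GRCH38_AUTOSOMES.sum())).astype(np.int64)
    scaled[0] += total - scaled.sum()  # absorb rounding residual on chr1
    return scaled


HUMAN_AUTOSOME_LENGTHS: np.ndarray = _rescaled_autosomes()


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome coordinate system with a uniform recombination rate.

    Parameters
    ----------
    chrom_lengths : sequence of int
        Physical length of each chromosome in bp. Defaults to the 22 human
        autosomes rescaled to a 2.88 Gb genome.
    recomb_rate : float
        Per-bp, per-generation crossover probability (default 1e-8, i.e.
        1 cM per Mb, 28.8 crossovers expected per gamete genome-wide).
    """

    chrom_lengths: np.ndarray = field(
        default_factory=lambda: HUMAN_AUTOSOME_LENGTHS.copy()
    )
    recomb_rate: float = DEFAULT_RECOMB_RATE

    def __post_init__(self) -> None:
        lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if lengths.ndim != 1 or lengths.size == 0:
            raise ValueError("chrom_lengths must be a non-empty 1-D sequence")
        if np.any(lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        object.__setattr__(self, "chrom_lengths", lengths)
        # cached derived coordinates (meiosis hot path)
        ends = np.cumsum(lengths)
        object.__setattr__(self, "_chrom_ends", ends)
        object.__setattr__(self, "_chrom_starts", ends - lengths)
        object.__setattr__(self, "_total_length", int(ends[-1]))

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom_lengths.size)

    @property
    def total_length(self) -> int:
        """Total genome size L in bp."""
        return self._total_length

    @property
    def chrom_starts(self) -> np.ndarray:
        """Global (concatenated-axis) start coordinate of each chromosome."""
        return self._chrom_starts

    @property
    def chrom_ends(self) -> np.ndarray:
        """Global end coordinate of each chromosome (cumulative lengths)."""
        return self._chrom_ends

    def bp_to_morgans(self, lengths_bp: np.ndarray | float) -> np.ndarray | float:
        """Convert physical length to genetic map length under the uniform rate."""
        return np.asarray(lengths_bp, dtype=float) * self.recomb_rate

    def chrom_of(self, position: np.ndarray) -> np.ndarray:
        """Chromosome index (0-based) containing each global position."""
        return np.searchsorted(self.chrom_ends, position, side="right")


class TractSet:
    """Source-labeled ancestry tracts for one haplotype, genome-wide.

    Stored as ``ends`` (strictly increasing global tract end coordinates,
    always containing every chromosome end, with ``ends[-1] == L``) and
    ``sources`` (1 or 2 per tract). Tracts exactly tile every chromosome and
    are maximally merged within chromosomes: two adjacent tracts on the same
    chromosome never share a source.
    """

    __slots__ = ("ends", "sources")

    def __init__(self, ends: np.ndarray, sources: np.ndarray):
        self.ends = np.asarray(ends, dtype=np.int64)
        self.sources = np.asarray(sources, dtype=np.uint8)

    @classmethod
    def single_source(cls, source: int, gmap: GenomeMap) -> "TractSet":
        """Founder haplotype: one tract per chromosome, all from one source."""
        if source not in (1, 2):
            raise ValueError("source must be 1 or 2")
        ends = gmap.chrom_ends
        return cls(ends, np.full(ends.size, source, dtype=np.uint8))

    @classmethod
    def from_chrom_tracts(
        cls,
        tracts_per_chrom: Sequence[Sequence[tuple[int, int, int]]],
        gmap: GenomeMap,
    ) -> "TractSet":
        """Build from per-chromosome ``(start, end, source)`` triples in local bp."""
        ends: list[int] = []
        sources: list[int] = []
        for c, tracts in enumerate(tracts_per_chrom):
            offset = int(gmap.chrom_starts[c])
            for start, end, source in tracts:
                ends.append(offset + end)
                sources.append(source)
        ts = cls(np.array(ends), np.array(sources))
        ts.validate(gmap)
        return ts

    def validate(self, gmap: GenomeMap) -> None:
        """Raise ValueError unless tracts tile the genome and are merged."""
        ends, sources = self.ends, self.sources
        if ends.size != sources.size or ends.size == 0:
            raise ValueError("ends and sources must be equal-length, non-empty")
        if ends[0] <= 0 or np.any(np.diff(ends) <= 0):
            raise ValueError("tract ends must be strictly increasing and positive")
        if ends[-1] != gmap.total_length:
            raise ValueError("tracts must tile the genome up to L")
        if not np.all(np.isin(gmap.chrom_ends, ends)):
            raise ValueError("every chromosome end must be a tract boundary")
        if not np.all(np.isin(sources, (1, 2))):
            raise ValueError("sources must be 1 or 2")
        # maximal merging: same-source neighbours only across chromosome ends
        same = sources[1:] == sources[:-1]
        at_chrom_end = np.isin(ends[:-1], gmap.chrom_ends)
        if np.any(same & ~at_chrom_end):
            raise ValueError("adjacent same-source tracts must be merged")

    def lengths(self) -> np.ndarray:
        """Length of every tract in bp."""
        e = self.ends
        w = np.empty(e.size, dtype=np.int64)
        w[0] = e[0]
        np.subtract(e[1:], e[:-1], out=w[1:])
        return w

    def source_bp(self, source: int) -> int:
        """Total bp inherited from `source` on this haplotype."""
        return int(self.lengths()[self.sources == source].sum())

    def n_tracts(self) -> int:
        return int(self.ends.size)

    def censored(self, gmap: GenomeMap) -> np.ndarray:
        """Boolean mask of tracts abutting a chromosome end (length-censored)."""
        starts = self.ends - self.lengths()
        return np.isin(starts, gmap.chrom_starts) | np.isin(self.ends, gmap.chrom_ends)

    def iter_chrom_tracts(
        self, gmap: GenomeMap
    ) -> Iterator[tuple[int, int, int, int]]:
        """Yield ``(chrom_index, start, end, source)`` with chromosome-local coords."""
        starts = self.ends - self.lengths()
        chroms = gmap.chrom_of(starts)
        offsets = gmap.chrom_starts[chroms]
        for c, s, e, src in zip(chroms, starts - offsets, self.ends - offsets, self.sources):
            yield int(c), int(s), int(e), int(src)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TractSet):
            return NotImplemented
        return np.array_equal(self.ends, other.ends) and np.array_equal(
            self.sources, other.sources
        )

    def __repr__(self) -> str:
        return f"TractSet(n_tracts={self.ends.size})"


@dataclass(eq=False)
class Individual:
    """A diploid individual: two tract haplotypes plus social attributes.

    ``x`` is the global ancestry proportion (fraction of the diploid genome
    derived from source population 1); ``group`` is the social group label,
    inherited from parent 1 and only initially coincident with source.
    """

    __slots__ = ("hap1", "hap2", "x", "group", "is_migrant", "id")

    hap1: TractSet
    hap2: TractSet
    x: float
    group: str
    is_migrant: bool
    id: int

    @classmethod
    def founder(
        cls, source: int, gmap: GenomeMap, id: int, is_migrant: bool = False
    ) -> "Individual":
        group = "A" if source == 1 else "B"
        x = 1.0 if source == 1 else 0.0
        return cls(
            hap1=TractSet.single_source(source, gmap),
            hap2=TractSet.single_source(source, gmap),
            x=x,
            group=group,
            is_migrant=is_migrant,
            id=id,
        )


def draw_crossovers(
    chrom_length: int, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw crossover positions on one chromosome.

    The number of crossovers is Poisson(``r * chrom_length``) and positions
    are i.i.d. uniform integers on ``[0, chrom_length)`` (no interference);
    coincident positions are deduplicated. Returns a sorted int64 array.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if r < 0:
        raise ValueError("recombination rate must be non-negative")
    n = rng.poisson(r * chrom_length)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(0, chrom_length, size=n))


def _sorted_unique(a: np.ndarray) -> np.ndarray:
    a = np.sort(a)
    if a.size <= 1:
        return a
    keep = np.empty(a.size, dtype=bool)
    keep[0] = True
    np.not_equal(a[1:], a[:-1], out=keep[1:])
    return a[keep]


def _gamete_from_switches(
    parent: Individual, bpos: np.ndarray, active: np.ndarray, gmap: GenomeMap
) -> TractSet:
    """Assemble a gamete given sorted switch-point positions and the haplotype
    (0 = hap1, 1 = hap2) active on each inter-switch segment."""
    h1e, h1s = parent.hap1.ends, parent.hap1.sources
    h2e, h2s = parent.hap2.ends, parent.hap2.sources
    # union grid of all segment start points (< L)
    cut = _sorted_unique(np.concatenate((bpos, h1e[:-1], h2e[:-1])))
    a = active[np.searchsorted(bpos, cut, side="right") - 1]
    s1 = h1s[np.searchsorted(h1e, cut, side="right")]
    s2 = h2s[np.searchsorted(h2e, cut, side="right")]
    src = np.where(a == 0, s1, s2)
    # merge equal-source neighbours, but never across chromosome boundaries
    starts = gmap.chrom_starts
    tail = cut[1:]
    pos = np.searchsorted(starts, tail)
    at_start = (pos < starts.size) & (starts[np.minimum(pos, starts.size - 1)] == tail)
    keep = np.empty(cut.size, dtype=bool)
    keep[0] = True
    keep[1:] = (src[1:] != src[:-1]) | at_start
    kept = cut[keep]
    ends = np.append(kept[1:], gmap.total_length)
    return TractSet(ends, src[keep])


def meiosis(parent: Individual, gmap: GenomeMap, rng: np.random.Generator) -> TractSet:
    """Produce one recombinant gamete from a parent.

    Each chromosome independently starts from a fair-coin choice of parental
    haplotype (independent assortment) and alternates haplotype at each
    crossover; crossover counts are Poisson with the uniform map rate. The
    returned gamete tiles the genome and is maximally merged.
    """
    L = gmap.total_length
    starts = gmap.chrom_starts
    n_xo = rng.poisson(gmap.recomb_rate * L)
    xo = (
        _sorted_unique(rng.integers(0, L, size=n_xo))
        if n_xo
        else np.empty(0, dtype=np.int64)
    )
    start_bits = rng.integers(0, 2, size=starts.size)

    bpos = np.concatenate((starts, xo))
    is_start = np.zeros(bpos.size, dtype=bool)
    is_start[: starts.size] = True
    order = np.argsort(bpos, kind="stable")  # ties: chromosome start first
    bpos = bpos[order]
    is_start = is_start[order]

    idx = np.arange(bpos.size)
    last_start = np.maximum.accumulate(np.where(is_start, idx, -1))
    flips = np.cumsum(~is_start)
    start_ordinal = np.cumsum(is_start) - 1
    active = (start_bits[start_ordinal[last_start]] + flips - flips[last_start]) % 2
    return _gamete_from_switches(parent, bpos, active, gmap)


def global_ancestry(ind: Individual, gmap: GenomeMap) -> float:
    """Fraction of the diploid genome derived from source population 1.

    Recomputed from the tracts: ``x = (source-1 bp on both haplotypes) / 2L``.
    """
    ind.hap1.validate(gmap)
    ind.hap2.validate(gmap)
    bp1 = ind.hap1.source_bp(1) + ind.hap2.source_bp(1)
    return bp1 / (2 * gmap.total_length)


def collect_tract_lengths(
    population: Iterable[Individual],
    source: int | str = "both",
    gmap: GenomeMap | None = None,
    return_censored: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Pool tract lengths (bp) of the requested source across a population.

    Lengths of maximally merged tracts over both haplotypes of every
    individual. Tracts abutting chromosome ends are included; pass
    ``return_censored=True`` (requires ``gmap``) to also get a boolean mask
    flagging those length-censored tracts.
    """
    population = list(population)
    if not population:
        raise ValueError("population must be non-empty")
    if source not in (1, 2, "both"):
        raise ValueError("source must be 1, 2 or 'both'")
    if return_censored and gmap is None:
        raise ValueError("gmap is required when return_censored=True")
    lengths: list[np.ndarray] = []
    censored: list[np.ndarray] = []
    for ind in population:
        for hap in (ind.hap1, ind.hap2):
            ln = hap.lengths()
            mask = (
                np.ones(ln.size, dtype=bool)
                if source == "both"
                else hap.sources == source
            )
            lengths.append(ln[mask])
            if return_censored:
                censored.append(hap.censored(gmap)[mask])
    out = np.concatenate(lengths)
    if return_censored:
        return out, np.concatenate(censored)
    return out
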