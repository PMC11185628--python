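"""Tract representation, crossover statistics and meiosis."""

import numpy as np
import pytest
from scipy import stats as sps

from admixmate import (
    GenomeMap,
    Individual,
    TractSet,
    collect_tract_lengths,
    draw_crossovers,
    global_ancestry,
    meiosis,
)


class TestGenomeMap:
    def test_default_is_22_autosomes_totalling_2p88_gb(self):
        gmap = GenomeMap()
        assert gmap.n_chromosomes == 22
        assert gmap.total_length == 2_880_000_000
        assert gmap.recomb_rate == 1e-8

    def test_one_cm_is_one_mb_at_default_rate(self):
        gmap = GenomeMap()
        assert gmap.bp_to_morgans(1_000_000) == pytest.approx(0.01)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            GenomeMap(chrom_lengths=np.array([0, 100]))
        with pytest.raises(ValueError):
            GenomeMap(chrom_lengths=np.array([100]), recomb_rate=-1e-8)


class TestDrawCrossovers:
    def test_zero_rate_gives_no_crossovers(self, rng):
        assert draw_crossovers(10**8, 0.0, rng).size == 0

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            draw_crossovers(-1, 1e-8, rng)
        with pytest.raises(ValueError):
            draw_crossovers(100, -1e-8, rng)

    def test_positions_sorted_unique_in_range(self, rng):
        pos = draw_crossovers(10**7, 1e-6, rng)  # ~10 expected
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 0 and pos.max() < 10**7

    def test_poisson_moments_at_mean_one(self, rng):
        """10^8 bp at 1e-8/bp: crossover count has mean 1 and variance 1."""
        counts = np.array([draw_crossovers(10**8, 1e-8, rng).size for _ in range(5000)])
        assert counts.mean() == pytest.approx(1.0, abs=4 / np.sqrt(5000))
        assert counts.var() == pytest.approx(1.0, abs=0.1)

    def test_poisson_goodness_of_fit(self, rng):
        """Counts on a mean-1 chromosome fit Poisson(1) by chi-square."""
        counts = np.array([draw_crossovers(10**8, 1e-8, rng).size for _ in range(4000)])
        observed = np.array([(counts == k).sum() for k in range(3)] + [(counts >= 3).sum()])
        pmf = sps.poisson(1.0).pmf(np.arange(3))
        expected = 4000 * np.append(pmf, 1 - pmf.sum())
        assert sps.chisquare(observed, expected).pvalue > 1e-3

    def test_genome_wide_mean_is_28_8(self, default_gmap, rng):
        """Expected crossovers per gamete across the 2.88 Gb genome: 28.8."""
        total = sum(
            draw_crossovers(int(ln), default_gmap.recomb_rate, rng).size
            for _ in range(500)
            for ln in default_gmap.chrom_lengths
        )
        mean = total / 500
        se = np.sqrt(28.8 / 500)
        assert mean == pytest.approx(28.8, abs=4 * se)


class TestTractSet:
    def test_founder_single_tract_per_chromosome(self, small_gmap):
        ts = TractSet.single_source(1, small_gmap)
        ts.validate(small_gmap)
        assert ts.n_tracts() == 2
        assert np.array_equal(ts.lengths(), small_gmap.chrom_lengths)

    def test_unmerged_tracts_rejected(self, small_gmap):
        with pytest.raises(ValueError):
            TractSet.from_chrom_tracts(
                [[(0, 10_000_000, 1), (10_000_000, 50_000_000, 1)],
                 [(0, 50_000_000, 2)]],
                small_gmap,
            )

    def test_tiling_gap_rejected(self, small_gmap):
        ts = TractSet(np.array([40_000_000, 100_000_000]), np.array([1, 2]))
        with pytest.raises(ValueError):
            ts.validate(small_gmap)

    def test_censored_flags_tracts_at_chromosome_ends(self, small_gmap):
        ts = TractSet.from_chrom_tracts(
            [[(0, 10_000_000, 1), (10_000_000, 30_000_000, 2), (30_000_000, 50_000_000, 1)],
             [(0, 50_000_000, 2)]],
            small_gmap,
        )
        assert ts.censored(small_gmap).tolist() == [True, False, True, True]


class TestMeiosis:
    def test_pure_parent_gives_pure_gamete(self, small_gmap, rng):
        parent = Individual.founder(1, small_gmap, id=0)
        gamete = meiosis(parent, small_gmap, rng)
        gamete.validate(small_gmap)
        assert np.all(gamete.sources == 1)
        assert gamete.source_bp(1) == small_gmap.total_length

    def test_zero_crossovers_returns_a_parental_haplotype(self, mixed_parent):
        gmap0 = GenomeMap(chrom_lengths=np.array([50_000_000] * 2), recomb_rate=0.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            gamete = meiosis(mixed_parent, gmap0, rng)
            gamete.validate(gmap0)
            # each chromosome is wholly source 1 or wholly source 2
            assert gamete.n_tracts() == 2
            assert set(gamete.sources) <= {1, 2}

    def test_gamete_tiles_genome_after_every_meiosis(self, small_gmap, mixed_parent, rng):
        for _ in range(200):
            meiosis(mixed_parent, small_gmap, rng).validate(small_gmap)

    def test_transmission_is_unbiased(self, mixed_parent, small_gmap, rng):
        """Mean gamete source-1 fraction equals the parent's x = 0.5."""
        n = 10_000
        L = small_gmap.total_length
        fracs = np.array(
            [meiosis(mixed_parent, small_gmap, rng).source_bp(1) / L for _ in range(n)]
        )
        se = fracs.std() / np.sqrt(n)
        assert fracs.mean() == pytest.approx(0.5, abs=3 * se)

    def test_recombinant_parent_transmission_matches_x(self, small_gmap, rng):
        """A parent with unequal ancestry transmits its own x on average."""
        hap1 = TractSet.from_chrom_tracts(
            [[(0, 30_000_000, 1), (30_000_000, 50_000_000, 2)], [(0, 50_000_000, 1)]],
            small_gmap,
        )
        hap2 = TractSet.single_source(2, small_gmap)
        parent = Individual(hap1=hap1, hap2=hap2, x=0.4, group="A", is_migrant=False, id=1)
        assert global_ancestry(parent, small_gmap) == pytest.approx(0.4)
        n, L = 4000, small_gmap.total_length
        fracs = np.array(
            [meiosis(parent, small_gmap, rng).source_bp(1) / L for _ in range(n)]
        )
        se = fracs.std() / np.sqrt(n)
        assert fracs.mean() == pytest.approx(0.4, abs=3 * se)


class TestGlobalAncestry:
    def test_founders(self, small_gmap):
        assert global_ancestry(Individual.founder(1, small_gmap, 0), small_gmap) == 1.0
        assert global_ancestry(Individual.founder(2, small_gmap, 1), small_gmap) == 0.0

    def test_half_and_half(self, small_gmap, mixed_parent):
        assert global_ancestry(mixed_parent, small_gmap) == pytest.approx(0.5)

    def test_direct_arithmetic_on_default_genome(self, default_gmap):
        """1.0e9 source-1 bp over both haplotypes of a 2.88 Gb genome: x ~= 0.17361."""
        L = default_gmap.total_length
        # hap1: first 1.0e9 bp (global) source 1; hap2 entirely source 2
        boundary = 1_000_000_000
        ce = default_gmap.chrom_ends
        ends = np.sort(np.unique(np.concatenate((ce, [boundary]))))
        sources = np.where(ends <= boundary, 1, 2).astype(np.uint8)
        hap1 = TractSet(ends, sources)
        hap1.validate(default_gmap)
        ind = Individual(
            hap1=hap1,
            hap2=TractSet.single_source(2, default_gmap),
            x=0.0, group="A", is_migrant=False, id=0,
        )
        assert global_ancestry(ind, default_gmap) == pytest.approx(
            1_000_000_000 / (2 * L), rel=1e-12
        )
        assert global_ancestry(ind, default_gmap) == pytest.approx(0.17361, abs=1e-5)


class TestCollectTractLengths:
    def test_founder_population_tracts_equal_chromosomes(self, small_gmap):
        pop = [Individual.founder(1, small_gmap, i) for i in range(3)]
        lengths = collect_tract_lengths(pop, source="both")
        assert lengths.size == 3 * 2 * small_gmap.n_chromosomes
        assert set(lengths.tolist()) == set(small_gmap.chrom_lengths.tolist())

    def test_single_crossover_splits_into_two_tracts(self):
        gmap = GenomeMap(chrom_lengths=np.array([100_000_000]), recomb_rate=1e-8)
        hap = TractSet.from_chrom_tracts(
            [[(0, 50_000_000, 1), (50_000_000, 100_000_000, 2)]], gmap
        )
        ind = Individual(hap1=hap, hap2=TractSet.single_source(1, gmap),
                         x=0.75, group="A", is_migrant=False, id=0)
        lengths = collect_tract_lengths([ind], source=1)
        assert sorted(lengths.tolist()) == [50_000_000, 100_000_000]

    def test_empty_population_is_an_error(self):
        with pytest.raises(ValueError):
            collect_tract_lengths([])

    def test_source_filter_partitions_all_tracts(self, small_gmap, mixed_parent, rng):
        child_hap = meiosis(mixed_parent, small_gmap, rng)
        ind = Individual(hap1=child_hap, hap2=child_hap, x=0.5, group="A",
                         is_migrant=False, id=0)
        both = collect_tract_lengths([ind], "both")
        s1 = collect_tract_lengths([ind], 1)
        s2 = collect_tract_lengths([ind], 2)
        assert s1.size + s2.size == both.size
        assert s1.sum() + s2.sum() == both.sum() == 2 * small_gmap.total_length
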