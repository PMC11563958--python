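"""Founder simulation, meiosis, crossing and single-seed descent."""

import numpy as np
import pytest

from breedsim.genome import (GenomeSpec, Population, advance_ssd,
                             make_crosses, meiosis,
                             sample_half_diallel_crosses, simulate_founders)

from .conftest import population_from_haplotypes, uniform_map


class TestSimulateFounders:
    def test_counts_and_roles(self, mini_spec, mini_founders):
        founders, gmap = mini_founders
        assert founders.n == mini_spec.n_founders
        assert gmap.qtl_idx.size == mini_spec.n_qtl
        assert gmap.marker_idx.size == mini_spec.n_markers
        assert not np.intersect1d(gmap.qtl_idx, gmap.marker_idx).size

    def test_every_locus_polymorphic(self, mini_founders):
        founders, _ = mini_founders
        freq = founders.allele_frequency()
        assert np.all((freq > 0) & (freq < 1))

    def test_minimal_sample_polymorphic(self):
        spec = GenomeSpec(n_chromosomes=1, n_qtl=10, n_markers=5,
                          n_founders=2, bp_per_chr=1e7)
        founders, gmap = simulate_founders(spec, seed=3)
        assert founders.n == 2
        freq = founders.allele_frequency()
        assert np.all((freq > 0) & (freq < 1))

    def test_raises_when_sites_insufficient(self):
        # a near-zero mutation rate cannot yield 100 segregating sites
        spec = GenomeSpec(n_chromosomes=1, n_qtl=80, n_markers=20,
                          n_founders=4, bp_per_chr=1e6, mutation_rate=1e-11)
        with pytest.raises(RuntimeError, match="segregating"):
            simulate_founders(spec, seed=1)

    def test_map_positions_sorted(self, mini_founders):
        _, gmap = mini_founders
        for c in range(gmap.n_chromosomes):
            seg = gmap.pos_morgan[gmap.chr_start[c]:gmap.chr_end[c]]
            assert np.all(np.diff(seg) > 0)

    def test_determinism(self, mini_spec):
        a, _ = simulate_founders(mini_spec, seed=5)
        b, _ = simulate_founders(mini_spec, seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)


def test_founder_diversity_matches_neutral_expectation():
    """Mean heterozygosity at retained sites reflects coalescent diversity.

    The neutral site-frequency spectrum at sample size 2n gives an
    expected 2p(1-p) per segregating site of (2/H) * sum_{i<2n} (i/2n) *
    (1 - i/2n) / i with H the harmonic number: the oracle is evaluated by
    direct enumeration and compared with the Monte-Carlo mean over seeds.
    """
    spec = GenomeSpec(n_chromosomes=2, n_qtl=60, n_markers=30,
                      n_founders=15, bp_per_chr=1e7)
    k = 2 * spec.n_founders
    i = np.arange(1, k)
    expected = np.sum((i / k) * (1 - i / k) / i) / np.sum(1.0 / i) * 2
    vals = []
    for seed in range(25):
        founders, gmap = simulate_founders(spec, seed=100 + seed)
        p = founders.allele_frequency()
        vals.append(float(np.mean(2 * p * (1 - p))))
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - expected) < 3 * se + 0.01


class TestMeiosis:
    def test_homozygous_parent_invariance(self, rng):
        gmap = uniform_map(100)
        hap = rng.integers(0, 2, 100).astype(np.int8)
        pop = population_from_haplotypes(np.stack([hap, hap])[None])
        gamete = meiosis(pop.individual(0), gmap, rng)
        assert np.array_equal(gamete, hap)

    def test_crossover_count_matches_poisson_model(self, rng):
        """Observed strand switches equal the exact odd-crossover sums.

        For loci at positions p_1..p_L the expected number of observable
        switches per gamete is sum over gaps of P(odd # crossovers in
        gap) = (1 - exp(-2 dx)) / 2 under the no-interference model.
        """
        gmap = uniform_map(n_loci=200, morgans=1.2)
        haps = np.stack([np.zeros(200, np.int8), np.ones(200, np.int8)])[None]
        pop = population_from_haplotypes(haps)
        from breedsim._meiosis import draw_gametes
        n = 100_000
        g = draw_gametes(pop.haplotypes, np.zeros(n, dtype=np.int64),
                         gmap.chr_start, gmap.chr_end, gmap.pos_morgan,
                         gmap.morgans, rng)
        switches = (np.diff(g.astype(np.int16), axis=1) != 0).sum(axis=1)
        gaps = np.diff(gmap.pos_morgan)
        expected = np.sum((1 - np.exp(-2 * gaps)) / 2)
        se = switches.std(ddof=1) / np.sqrt(n)
        assert abs(switches.mean() - expected) < 3 * se

    def test_two_locus_recombination_follows_haldane(self, rng):
        """Recombinant fraction at 0.5 M equals (1 - e^-1)/2."""
        per = 2
        gmap = uniform_map(n_loci=2, morgans=1.2)
        gmap.pos_morgan[:] = [0.3, 0.8]
        haps = np.stack([np.zeros(per, np.int8), np.ones(per, np.int8)])[None]
        pop = population_from_haplotypes(haps)
        from breedsim._meiosis import draw_gametes
        n = 200_000
        g = draw_gametes(pop.haplotypes, np.zeros(n, dtype=np.int64),
                         gmap.chr_start, gmap.chr_end, gmap.pos_morgan,
                         gmap.morgans, rng)
        rec = (g[:, 0] != g[:, 1]).mean()
        expected = (1 - np.exp(-2 * 0.5)) / 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 3 * se


class TestCrossing:
    def test_f1_bookkeeping(self, mini_founders, rng):
        founders, gmap = mini_founders
        plan = sample_half_diallel_crosses(founders, 10, rng)
        f1 = make_crosses(founders, gmap, plan, 12, rng)
        assert f1.n == 120
        assert len(np.unique(f1.family)) == 10
        assert np.all(np.bincount(f1.family) == 12)
        assert f1.generation == "F1"

    def test_identical_inbred_parents_give_parental_genotype(self, rng):
        gmap = uniform_map(60)
        hap = rng.integers(0, 2, 60).astype(np.int8)
        haps = np.stack([np.stack([hap, hap]), np.stack([hap, hap])])
        parents = population_from_haplotypes(haps)
        f1 = make_crosses(parents, gmap, [(0, 1)], 5, rng)
        assert np.all(f1.haplotypes == hap[None, None, :])

    def test_unknown_parent_and_selfing_rejected(self, mini_founders, rng):
        founders, gmap = mini_founders
        with pytest.raises(KeyError):
            make_crosses(founders, gmap, [(0, 10_000)], 1, rng)
        with pytest.raises(ValueError, match="[Ss]elf"):
            make_crosses(founders, gmap, [(3, 3)], 1, rng)

    def test_allele_conservation(self, mini_founders, rng):
        """No descendant carries an allele absent from the founders."""
        founders, gmap = mini_founders
        plan = sample_half_diallel_crosses(founders, 5, rng)
        f4 = advance_ssd(make_crosses(founders, gmap, plan, 10, rng),
                         gmap, 3, rng)
        f_freq = founders.allele_frequency()
        d_freq = f4.allele_frequency()
        # loci fixed in the founders cannot segregate downstream
        assert np.all(d_freq[f_freq == 0] == 0)
        assert np.all(d_freq[f_freq == 1] == 1)
        assert set(np.unique(f4.haplotypes)) <= {0, 1}


class TestSingleSeedDescent:
    def test_size_and_label_conserved(self, mini_founders, rng):
        founders, gmap = mini_founders
        plan = sample_half_diallel_crosses(founders, 8, rng)
        f1 = make_crosses(founders, gmap, plan, 15, rng)
        f6 = advance_ssd(f1, gmap, 5, rng)
        assert f6.n == f1.n
        assert f6.generation == "F6"
        assert np.array_equal(f6.family, f1.family)

    def test_fixation_is_absorbing(self, rng):
        gmap = uniform_map(50)
        hap = rng.integers(0, 2, 50).astype(np.int8)
        pop = population_from_haplotypes(np.stack([hap, hap])[None])
        out = advance_ssd(pop, gmap, 7, rng)
        assert np.array_equal(out.haplotypes, pop.haplotypes)

    def test_heterozygosity_halves_each_generation(self, mini_founders, rng):
        founders, gmap = mini_founders
        plan = sample_half_diallel_crosses(founders, 10, rng)
        f1 = make_crosses(founders, gmap, plan, 200, rng)
        h1 = f1.heterozygosity().mean()
        pop, ratios = f1, []
        for _ in range(4):
            nxt = advance_ssd(pop, gmap, 1, rng)
            ratios.append(nxt.heterozygosity().mean()
                          / pop.heterozygosity().mean())
            pop = nxt
        # each selfing halves expected heterozygosity; 3 sigma of the
        # per-locus binomial averaging over ~2000 lines x 180 loci
        assert np.allclose(ratios, 0.5, atol=0.02)
        assert abs(pop.heterozygosity().mean() - h1 / 16) < h1 * 0.02

    def test_empty_and_invalid_args(self, mini_founders, rng):
        founders, gmap = mini_founders
        with pytest.raises(ValueError):
            advance_ssd(founders, gmap, 0, rng)


class TestHalfDiallel:
    def test_forced_single_pair(self, mini_founders, rng):
        founders, _ = mini_founders
        two = founders.subset([0, 1])
        plan = sample_half_diallel_crosses(two, 1, rng)
        assert sorted(plan[0].tolist()) == sorted(two.ids.tolist())

    def test_exhaustive_case_yields_all_pairs(self, mini_founders, rng):
        founders, _ = mini_founders
        five = founders.subset(range(5))
        plan = sample_half_diallel_crosses(five, 10, rng)
        pairs = {frozenset(p) for p in plan.tolist()}
        assert len(pairs) == 10

    def test_distinct_pairs_no_selfing(self, mini_founders, rng):
        founders, _ = mini_founders
        plan = sample_half_diallel_crosses(founders, 30, rng)
        pairs = {frozenset(p) for p in plan.tolist()}
        assert len(pairs) == 30
        assert all(len(p) == 2 for p in pairs)

    def test_infeasible_count_rejected(self, mini_founders, rng):
        founders, _ = mini_founders
        with pytest.raises(ValueError):
            sample_half_diallel_crosses(founders.subset([0, 1, 2]), 4, rng)

    def test_sampling_is_uniform_over_pairs(self, mini_founders):
        founders, _ = mini_founders
        five = founders.subset(range(5))
        counts = {}
        for seed in range(600):
            plan = sample_half_diallel_crosses(five, 3, seed)
            for p in plan.tolist():
                counts[frozenset(p)] = counts.get(frozenset(p), 0) + 1
        # each of the 10 pairs should appear ~180 times (600 draws x 3/10)
        obs = np.array(list(counts.values()))
        assert len(counts) == 10
        assert np.all(np.abs(obs - 180) < 5 * np.sqrt(180))
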