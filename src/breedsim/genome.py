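"""Founder genomes, meiosis, crossing and single-seed-descent line fixation.

Founder haplotypes are drawn from a neutral coalescent with recombination
(msprime), one independent tree sequence per chromosome, under a
constant-size population of effective size ``effective_pop_size``.  A
genotyping panel and a trait map are then carved out of the segregating
sites: QTL and marker loci are placed on disjoint, evenly spaced grids in
genetic-map position, each grid point snapped to the nearest unused
segregating site.  Downstream of the founders there is no mutation; all
variation in any descendant traces back to a founder haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from ._meiosis import draw_gametes

__all__ = [
    "GenomeSpec",
    "GeneticMap",
    "Population",
    "Individual",
    "simulate_founders",
    "meiosis",
    "make_crosses",
    "advance_ssd",
    "sample_half_diallel_crosses",
    "as_rng",
    "write_founder_vcf",
    "write_map_tsv",
]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the simulated rice-like genome.

    Defaults describe a 12-chromosome genome of 1.20 Morgans and 3x10^7 bp
    per chromosome, mutation rate 2.5x10^-8 per bp per generation,
    coalescent effective population size 60, and 80 non-inbred founders,
    carrying 3,000 QTL and a 1,200-SNP genotyping panel.
    """

    n_chromosomes: int = 12
    morgans_per_chr: float = 1.20
    bp_per_chr: float = 3e7
    mutation_rate: float = 2.5e-8
    effective_pop_size: int = 60
    n_founders: int = 80
    n_qtl: int = 3000
    n_markers: int = 1200

    def __post_init__(self):
        for name in ("n_chromosomes", "morgans_per_chr", "bp_per_chr",
                     "mutation_rate", "effective_pop_size", "n_founders",
                     "n_qtl", "n_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GenomeSpec.{name} must be strictly positive")

    @property
    def recombination_rate(self) -> float:
        """Uniform per-bp recombination rate (Morgans / bp)."""
        return self.morgans_per_chr / self.bp_per_chr

    def with_(self, **kw) -> "GenomeSpec":
        return replace(self, **kw)


@dataclass
class GeneticMap:
    """Ordered loci of all chromosomes with their roles.

    ``pos_morgan`` is the within-chromosome genetic position; loci are
    sorted by (chromosome, position) and QTL/marker sets are disjoint.
    """

    chrom: np.ndarray        # (L,) int32, 0-based chromosome index
    pos_bp: np.ndarray       # (L,) float64
    pos_morgan: np.ndarray   # (L,) float64, within-chromosome
    is_qtl: np.ndarray       # (L,) bool
    morgans_per_chr: float
    chr_start: np.ndarray = field(init=False)  # (C,) int64
    chr_end: np.ndarray = field(init=False)    # (C,) int64

    def __post_init__(self):
        n_chrom = int(self.chrom.max()) + 1
        self.chr_start = np.searchsorted(self.chrom, np.arange(n_chrom)).astype(np.int64)
        self.chr_end = np.searchsorted(self.chrom, np.arange(n_chrom), side="right").astype(np.int64)
        for c in range(n_chrom):
            seg = self.pos_morgan[self.chr_start[c]:self.chr_end[c]]
            if np.any(np.diff(seg) <= 0):
                raise ValueError("locus positions must be strictly increasing per chromosome")

    @property
    def n_loci(self) -> int:
        return self.chrom.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.chr_start.shape[0]

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def morgans(self) -> np.ndarray:
        return np.full(self.n_chromosomes, self.morgans_per_chr)


@dataclass
class Population:
    """A set of diploid individuals stored as stacked haplotype arrays."""

    haplotypes: np.ndarray          # (n, 2, L) int8, alleles in {0, 1}
    ids: np.ndarray                 # (n,) int64, unique within population
    parents: np.ndarray             # (n, 2) int64, -1 for founders
    family: np.ndarray              # (n,) int64, cross of origin (-1 founders)
    generation: str = "F0"
    stage: str = "FOUNDER"
    year: int = 0

    def __post_init__(self):
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if len(np.unique(self.ids)) != self.n:
            raise ValueError("individual ids must be unique within a population")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosage(self, loci=None) -> np.ndarray:
        """Scaled allele dosage in {-1, 0, +1}; homozygotes map to ±1."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return (h[:, 0, :].astype(np.int16) + h[:, 1, :] - 1).astype(np.int8)

    def allele_frequency(self, loci=None) -> np.ndarray:
        """Frequency of the allele coded 1."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.mean(axis=(0, 1))

    def heterozygosity(self) -> np.ndarray:
        """Per-locus observed heterozygosity."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=0)

    def subset(self, idx, **overrides) -> "Population":
        idx = np.asarray(idx)
        kw = dict(generation=self.generation, stage=self.stage, year=self.year)
        kw.update(overrides)
        return Population(self.haplotypes[idx].copy(), self.ids[idx].copy(),
                          self.parents[idx].copy(), self.family[idx].copy(), **kw)

    def copy(self) -> "Population":
        return self.subset(np.arange(self.n))

    def individual(self, i: int) -> "Individual":
        return Individual(int(self.ids[i]), self.haplotypes[i],
                          tuple(self.parents[i]), self.generation,
                          int(self.family[i]))

    @staticmethod
    def concatenate(pops, **overrides) -> "Population":
        kw = dict(generation=pops[0].generation, stage=pops[0].stage,
                  year=pops[0].year)
        kw.update(overrides)
        n_tot = sum(p.n for p in pops)
        ids = np.arange(n_tot, dtype=np.int64)
        return Population(
            np.concatenate([p.haplotypes for p in pops]),
            ids,
            np.concatenate([p.parents for p in pops]),
            np.concatenate([p.family for p in pops]),
            **kw,
        )


@dataclass
class Individual:
    """Read-only view of a single diploid line."""

    id: int
    haplotypes: np.ndarray  # (2, L) int8
    parents: tuple
    generation_label: str
    family_id: int


def simulate_founders(spec: GenomeSpec, seed: int):
    """Simulate founder diploids and build the locus map.

    One coalescent-with-recombination tree sequence is simulated per
    chromosome (constant population size ``effective_pop_size``), binary
    mutations are laid down at ``mutation_rate``, and QTL/marker loci are
    selected from the segregating sites on disjoint even grids.

    Returns
    -------
    (Population, GeneticMap)

    Raises
    ------
    RuntimeError
        If any chromosome yields fewer polymorphic sites than the QTL +
        marker requirement.
    """
    rng_seeds = np.random.SeedSequence(seed).generate_state(2 * spec.n_chromosomes)
    qtl_per_chr = _split_counts(spec.n_qtl, spec.n_chromosomes)
    mrk_per_chr = _split_counts(spec.n_markers, spec.n_chromosomes)

    hap_blocks, chrom_col, bp_col, qtl_col = [], [], [], []
    for c in range(spec.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=spec.n_founders,
            population_size=spec.effective_pop_size,
            sequence_length=spec.bp_per_chr,
            recombination_rate=spec.recombination_rate,
            random_seed=int(rng_seeds[2 * c] % (2**31 - 1)) + 1,
        )
        ts = msprime.sim_mutations(
            ts,
            rate=spec.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng_seeds[2 * c + 1] % (2**31 - 1)) + 1,
        )
        geno = ts.genotype_matrix()          # (S, 2 * n_founders)
        pos = ts.tables.sites.position
        freq = geno.mean(axis=1)
        poly = (freq > 0) & (freq < 1)
        geno, pos = geno[poly], pos[poly]
        need = qtl_per_chr[c] + mrk_per_chr[c]
        if geno.shape[0] < need:
            raise RuntimeError(
                f"chromosome {c}: {geno.shape[0]} segregating sites, "
                f"but {need} QTL+marker loci requested"
            )
        qtl_sites = _grid_sites(pos, qtl_per_chr[c], spec.bp_per_chr, set())
        mrk_sites = _grid_sites(pos, mrk_per_chr[c], spec.bp_per_chr,
                                set(qtl_sites))
        keep = np.array(sorted(set(qtl_sites) | set(mrk_sites)))
        qtl_col.append(np.isin(keep, qtl_sites))
        hap_blocks.append(geno[keep].T.astype(np.int8))  # (2n, L_c)
        chrom_col.append(np.full(keep.size, c, dtype=np.int32))
        bp_col.append(pos[keep])

    haps = np.concatenate(hap_blocks, axis=1)
    n = spec.n_founders
    haplotypes = haps.reshape(n, 2, -1)
    gmap = GeneticMap(
        chrom=np.concatenate(chrom_col),
        pos_bp=np.concatenate(bp_col),
        pos_morgan=np.concatenate(bp_col) * spec.recombination_rate,
        is_qtl=np.concatenate(qtl_col),
        morgans_per_chr=spec.morgans_per_chr,
    )
    founders = Population(
        haplotypes=np.ascontiguousarray(haplotypes),
        ids=np.arange(n, dtype=np.int64),
        parents=np.full((n, 2), -1, dtype=np.int64),
        family=np.full(n, -1, dtype=np.int64),
        generation="F0",
        stage="FOUNDER",
        year=0,
    )
    return founders, gmap


def _split_counts(total: int, k: int) -> np.ndarray:
    """Distribute `total` loci over `k` chromosomes as evenly as possible."""
    base = np.full(k, total // k, dtype=int)
    base[: total % k] += 1
    return base


def _grid_sites(pos: np.ndarray, k: int, length: float, taken: set) -> np.ndarray:
    """Snap an even grid of k points to the nearest unused sites."""
    chosen: set = set()
    grid = (np.arange(k) + 0.5) / k * length
    for target in grid:
        best = -1
        for cand in np.argsort(np.abs(pos - target)):
            cand = int(cand)
            if cand not in taken and cand not in chosen:
                best = cand
                break
        if best < 0:
            raise RuntimeError("not enough free segregating sites for the grid")
        chosen.add(best)
    return np.array(sorted(chosen))


def _gametes(pop: Population, gmap: GeneticMap, parent_idx, rng):
    return draw_gametes(pop.haplotypes, parent_idx, gmap.chr_start,
                        gmap.chr_end, gmap.pos_morgan, gmap.morgans, rng)


def meiosis(parent: Individual, gmap: GeneticMap, rng) -> np.ndarray:
    """One haploid gamete from `parent` (mosaic of its two haplotypes)."""
    rng = as_rng(rng)
    haps = parent.haplotypes[None, :, :]
    return draw_gametes(haps, np.zeros(1, dtype=np.int64), gmap.chr_start,
                        gmap.chr_end, gmap.pos_morgan, gmap.morgans, rng)[0]


def make_crosses(parents: Population, gmap: GeneticMap, cross_plan,
                 progeny_per_cross: int, seed) -> Population:
    """F1 progeny from a list of (parent_id, parent_id) pairs.

    Each F1 receives one independent gamete from each parent;
    ``family`` is the index of the cross in the plan.
    """
    rng = as_rng(seed)
    plan = np.asarray(cross_plan, dtype=np.int64)
    if plan.ndim != 2 or plan.shape[1] != 2:
        raise ValueError("cross_plan must be a sequence of parent-id pairs")
    if np.any(plan[:, 0] == plan[:, 1]):
        raise ValueError("self-crosses are not allowed in a cross plan")
    id_to_row = {int(i): r for r, i in enumerate(parents.ids)}
    try:
        rows = np.array([[id_to_row[int(a)], id_to_row[int(b)]] for a, b in plan])
    except KeyError as e:
        raise KeyError(f"unknown parent id {e.args[0]} in cross plan") from None
    n_cross = plan.shape[0]
    mother = np.repeat(rows[:, 0], progeny_per_cross)
    father = np.repeat(rows[:, 1], progeny_per_cross)
    n = n_cross * progeny_per_cross
    # interleave (mother, father) gametes so a contiguous (2n, L) buffer
    # reshapes to (n, 2, L)
    both = np.stack([mother, father], axis=1).ravel()
    buf = np.empty((2 * n, parents.n_loci), dtype=np.int8)
    draw_gametes(parents.haplotypes, both, gmap.chr_start, gmap.chr_end,
                 gmap.pos_morgan, gmap.morgans, rng, out=buf)
    haps = buf.reshape(n, 2, parents.n_loci)
    return Population(
        haplotypes=haps,
        ids=np.arange(n, dtype=np.int64),
        parents=np.stack([parents.ids[mother], parents.ids[father]], axis=1),
        family=np.repeat(np.arange(n_cross, dtype=np.int64), progeny_per_cross),
        generation="F1",
        stage="RGA",
        year=parents.year,
    )


_GEN_NUMBER = {"F%d" % i: i for i in range(1, 30)}


def advance_ssd(pop: Population, gmap: GeneticMap, n_generations: int,
                seed) -> Population:
    """Advance every line by selfing, one seed per line per generation.

    Population size, ids, family and pedigree labels are conserved; only
    the haplotypes change.  The generation label F_k is incremented once
    per selfing generation.
    """
    if pop.n == 0:
        raise ValueError("cannot advance an empty population")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = as_rng(seed)
    haps = np.ascontiguousarray(pop.haplotypes)
    selfed = np.repeat(np.arange(pop.n, dtype=np.int64), 2)
    for _ in range(n_generations):
        buf = np.empty((2 * pop.n, pop.n_loci), dtype=np.int8)
        draw_gametes(haps, selfed, gmap.chr_start, gmap.chr_end,
                     gmap.pos_morgan, gmap.morgans, rng, out=buf)
        haps = buf.reshape(pop.n, 2, pop.n_loci)
    gen_no = _GEN_NUMBER.get(pop.generation)
    label = f"F{gen_no + n_generations}" if gen_no else pop.generation
    return Population(haps, pop.ids.copy(), pop.parents.copy(),
                      pop.family.copy(), label, pop.stage, pop.year)


def sample_half_diallel_crosses(parents: Population, n_crosses: int,
                                seed) -> np.ndarray:
    """Uniformly sample distinct unordered parent pairs (no selfing)."""
    rng = as_rng(seed)
    n = parents.n
    n_pairs = n * (n - 1) // 2
    if n_crosses > n_pairs:
        raise ValueError(
            f"{n_crosses} crosses requested but only {n_pairs} distinct pairs exist"
        )
    pick = rng.choice(n_pairs, size=n_crosses, replace=False)
    # enumerate unordered pairs (i < j) lexicographically
    i = np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * pick)) / 2).astype(np.int64)
    j = (pick - i * (2 * n - i - 1) // 2 + i + 1).astype(np.int64)
    return np.stack([parents.ids[i], parents.ids[j]], axis=1)


def write_founder_vcf(path, pop: Population, gmap: GeneticMap) -> None:
    """Write phased biallelic founder genotypes as an uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsim\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"founder_{i}" for i in pop.ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n")
        role = np.where(gmap.is_qtl, "QTL", "MARKER")
        for l in range(gmap.n_loci):
            gt = "\t".join(
                f"{pop.haplotypes[i, 0, l]}|{pop.haplotypes[i, 1, l]}"
                for i in range(pop.n)
            )
            fh.write(
                f"chr{gmap.chrom[l] + 1}\t{int(gmap.pos_bp[l]) + 1}\t"
                f"{role[l]}_{l}\tA\tT\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_map_tsv(path, gmap: GeneticMap) -> None:
    """Write the locus map as TSV: chrom, bp, Morgan, role."""
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tmorgan\trole\n")
        for l in range(gmap.n_loci):
            role = "QTL" if gmap.is_qtl[l] else "MARKER"
            fh.write(f"{gmap.chrom[l] + 1}\t{gmap.pos_bp[l]:.1f}\t"
                     f"{gmap.pos_morgan[l]:.6f}\t{role}\n")
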