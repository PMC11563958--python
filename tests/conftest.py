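"""Shared fixtures: a small founder population and derived objects.

The miniature genome (3 chromosomes, 120 QTL, 60 markers, 20 founders)
keeps coalescent simulation and meiosis fast while preserving every
structural property of the full-size configuration.
"""

import numpy as np
import pytest

from breedsim.genome import GenomeSpec, GeneticMap, Population, simulate_founders
from breedsim.trait import TraitSpec, assign_trait


@pytest.fixture(scope="session")
def mini_spec():
    return GenomeSpec(n_chromosomes=3, n_qtl=120, n_markers=60,
                      n_founders=20, bp_per_chr=1e7)


@pytest.fixture(scope="session")
def mini_founders(mini_spec):
    founders, gmap = simulate_founders(mini_spec, seed=42)
    return founders, gmap


@pytest.fixture(scope="session")
def mini_arch(mini_founders):
    founders, gmap = mini_founders
    return assign_trait(founders, gmap, TraitSpec(), seed=7)


@pytest.fixture(scope="session")
def mini_arch_gei(mini_founders):
    founders, gmap = mini_founders
    return assign_trait(founders, gmap, TraitSpec(gei_variance=4.0), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_map(n_loci=200, morgans=1.2, n_chromosomes=1):
    """A hand-built map with evenly spaced loci, for meiosis oracles."""
    per = n_loci // n_chromosomes
    pos = np.linspace(0.0, morgans, per, endpoint=False) + morgans / (2 * per)
    return GeneticMap(
        chrom=np.repeat(np.arange(n_chromosomes, dtype=np.int32), per),
        pos_bp=np.tile(pos, n_chromosomes) * 1e6,
        pos_morgan=np.tile(pos, n_chromosomes),
        is_qtl=np.ones(per * n_chromosomes, dtype=bool),
        morgans_per_chr=morgans,
    )


def population_from_haplotypes(haps):
    haps = np.asarray(haps, dtype=np.int8)
    n = haps.shape[0]
    return Population(
        haplotypes=haps,
        ids=np.arange(n, dtype=np.int64),
        parents=np.full((n, 2), -1, dtype=np.int64),
        family=np.zeros(n, dtype=np.int64),
    )
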