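"""Trait architecture: additive + genotype-by-environment genetic values.

The genetic value of a line is

    GV = mu + sum_q a_q x_q + w * sum_q g_q x_q

with x_q the scaled QTL dosage in {-1, 0, +1}, ``a`` per-QTL additive
effects, ``g`` per-QTL interaction effects, and ``w`` a yearly standard
normal environmental covariate shared by every trial of that year.
Effects are drawn i.i.d. standard normal and affinely rescaled against
the founder population so that the additive component has mean exactly
``mu`` (0) and variance exactly ``sigma2_additive`` (1), and the
genotype-specific slope has variance ``sigma2_gei`` (0, 4 or 8).

Phenotypes add a normal error deviate whose variance is anchored once to
the founder additive variance through the stage heritability
(``sigma2_e = sigma2_A (1 - H2) / H2``); it is never re-estimated as
variance erodes, so realized heritability declines over the cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome import GeneticMap, Individual, Population, as_rng

__all__ = [
    "TraitSpec",
    "TraitArchitecture",
    "EnvironmentDraw",
    "assign_trait",
    "genetic_values",
    "genetic_value",
    "error_variance",
    "phenotype",
    "write_trait_tsv",
    "read_trait_tsv",
]


@dataclass(frozen=True)
class TraitSpec:
    """Calibration targets for the simulated trait (grain yield)."""

    mean: float = 0.0
    additive_variance: float = 1.0
    gei_variance: float = 0.0  # 0 = none, 4 = intermediate, 8 = high

    def __post_init__(self):
        if self.additive_variance <= 0:
            raise ValueError("additive_variance must be positive")
        if self.gei_variance < 0:
            raise ValueError("gei_variance must be non-negative")


@dataclass(frozen=True)
class EnvironmentDraw:
    """The random environmental component of GEI for one evaluation year."""

    year: int
    w: float


@dataclass
class TraitArchitecture:
    """Calibrated QTL effects over a genetic map."""

    qtl_idx: np.ndarray        # (nQTL,) locus indices into the map
    additive_effects: np.ndarray  # (nQTL,) a
    gei_effects: np.ndarray       # (nQTL,) g (all zero when gei_variance=0)
    intercept: float              # mu
    spec: TraitSpec = field(default_factory=TraitSpec)

    @property
    def n_qtl(self) -> int:
        return self.qtl_idx.size

    def favorable_dosage_value(self) -> np.ndarray:
        """GV contribution of the favorable homozygote at each QTL: |a|."""
        return np.abs(self.additive_effects)


def assign_trait(founders: Population, gmap: GeneticMap, spec: TraitSpec,
                 seed) -> TraitArchitecture:
    """Sample and calibrate QTL effects against the founder population.

    Raises if any QTL is monomorphic in the founders (the affine rescaling
    is then undefined).
    """
    rng = as_rng(seed)
    qtl_idx = gmap.qtl_idx
    x = founders.dosage(qtl_idx).astype(np.float64)  # (n, nQTL) in {-1,0,1}
    freq = founders.allele_frequency(qtl_idx)
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("founders are monomorphic at one or more QTL")

    a = rng.standard_normal(qtl_idx.size)
    v = x @ a
    sd = v.std()  # ddof=0: exact population variance of the founder sample
    if sd == 0:
        raise ValueError("degenerate founder additive values")
    a /= sd / np.sqrt(spec.additive_variance)
    intercept = spec.mean - float(np.mean(x @ a))

    g = rng.standard_normal(qtl_idx.size)
    if spec.gei_variance > 0:
        s = x @ g
        g /= s.std() / np.sqrt(spec.gei_variance)
    else:
        g = np.zeros_like(g)

    return TraitArchitecture(qtl_idx=qtl_idx, additive_effects=a,
                             gei_effects=g, intercept=intercept, spec=spec)


@njit(cache=True)
def _gv_sums(haps, qtl_idx, a, g):
    """Per-individual additive and GEI-slope sums over the QTL."""
    n = haps.shape[0]
    out_a = np.empty(n)
    out_g = np.empty(n)
    for i in range(n):
        sa = 0.0
        sg = 0.0
        for j in range(qtl_idx.shape[0]):
            l = qtl_idx[j]
            x = haps[i, 0, l] + haps[i, 1, l] - 1
            if x != 0:
                sa += x * a[j]
                sg += x * g[j]
        out_a[i] = sa
        out_g[i] = sg
    return out_a, out_g


def genetic_values(pop: Population, arch: TraitArchitecture,
                   w: float = 0.0) -> np.ndarray:
    """True genetic values of a population; ``w=0`` gives the main effect."""
    sa, sg = _gv_sums(np.ascontiguousarray(pop.haplotypes), arch.qtl_idx,
                      arch.additive_effects, arch.gei_effects)
    gv = arch.intercept + sa
    if w != 0.0:
        gv = gv + w * sg
    return gv


def genetic_value(ind: Individual, arch: TraitArchitecture,
                  env: EnvironmentDraw | None = None) -> float:
    """Genetic value of a single individual under one environment draw."""
    x = (ind.haplotypes[0, arch.qtl_idx].astype(np.float64)
         + ind.haplotypes[1, arch.qtl_idx] - 1.0)
    gv = arch.intercept + x @ arch.additive_effects
    if env is not None and env.w != 0.0:
        gv += env.w * (x @ arch.gei_effects)
    return float(gv)


def error_variance(arch: TraitArchitecture, h2: float) -> float:
    """Per-plot error variance anchored to the founder additive variance."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    s2a = arch.spec.additive_variance
    return s2a * (1.0 - h2) / h2


def phenotype(pop: Population, arch: TraitArchitecture, h2: float,
              n_locations: int, n_reps: int, env: EnvironmentDraw,
              seed) -> np.ndarray:
    """Trial-mean phenotypes: GV under ``env`` plus a mean error deviate.

    The error variance of the line mean is the per-plot error variance
    divided by ``n_locations * n_reps``; the environmental covariate is
    shared by all locations of the trial year.
    """
    rng = as_rng(seed)
    s2e = error_variance(arch, h2) / (n_locations * n_reps)
    gv = genetic_values(pop, arch, w=env.w)
    return gv + rng.normal(0.0, np.sqrt(s2e), size=pop.n)


def write_trait_tsv(path, gmap: GeneticMap, arch: TraitArchitecture) -> None:
    """Export the architecture as TSV (chrom, bp, a, g) for reproducibility."""
    with open(path, "w") as fh:
        fh.write(f"# intercept\t{float(arch.intercept)!r}\n")
        fh.write("chrom\tbp\ta\tg\n")
        for i, l in enumerate(arch.qtl_idx):
            fh.write(f"{gmap.chrom[l] + 1}\t{gmap.pos_bp[l]:.1f}\t"
                     f"{float(arch.additive_effects[i])!r}\t"
                     f"{float(arch.gei_effects[i])!r}\n")


def read_trait_tsv(path, gmap: GeneticMap, spec: TraitSpec | None = None
                   ) -> TraitArchitecture:
    """Re-import an architecture written by :func:`write_trait_tsv`."""
    a, g = [], []
    with open(path) as fh:
        header = fh.readline().split("\t")
        intercept = float(header[1])
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            a.append(float(parts[2]))
            g.append(float(parts[3]))
    return TraitArchitecture(qtl_idx=gmap.qtl_idx,
                             additive_effects=np.array(a),
                             gei_effects=np.array(g),
                             intercept=intercept,
                             spec=spec or TraitSpec())
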