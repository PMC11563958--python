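"""Low-level gamete formation kernel.

Crossovers are placed under a no-interference model: the count per
chromosome is Poisson with mean equal to the chromosome's genetic length
in Morgans, positions are uniform on the genetic map, and each chromosome
starts from a uniformly chosen parental haplotype.  The kernel itself is
pure bookkeeping: it copies haplotype segments between crossover
breakpoints, so its cost scales with the number of loci actually carried,
not with physical genome size.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _build_gametes(
    haplotypes,  # (n_parents, 2, L) int8
    parent_idx,  # (G,) int64: source parent of each gamete
    start_hap,  # (G, C) int8: haplotype each chromosome starts from
    xo_counts,  # (G, C) int64: crossovers per gamete x chromosome
    xo_pos,  # (K,) float64: crossover positions, grouped by (g, c)
    chr_start,  # (C,) int64: first locus index of each chromosome
    chr_end,  # (C,) int64: one-past-last locus index
    locus_pos,  # (L,) float64: within-chromosome Morgan position, sorted
    out,  # (G, L) int8
):
    n_gametes = parent_idx.shape[0]
    n_chrom = chr_start.shape[0]
    k = 0
    for g in range(n_gametes):
        p = parent_idx[g]
        for c in range(n_chrom):
            lo = chr_start[c]
            hi = chr_end[c]
            h = int(start_hap[g, c])
            n_xo = xo_counts[g, c]
            # insertion sort of this gamete/chromosome's breakpoints
            for i in range(k + 1, k + n_xo):
                key = xo_pos[i]
                j = i - 1
                while j >= k and xo_pos[j] > key:
                    xo_pos[j + 1] = xo_pos[j]
                    j -= 1
                xo_pos[j + 1] = key
            cur = lo
            for i in range(k, k + n_xo):
                # first locus at genetic position >= breakpoint
                a, b = lo, hi
                x = xo_pos[i]
                while a < b:
                    mid = (a + b) // 2
                    if locus_pos[mid] < x:
                        a = mid + 1
                    else:
                        b = mid
                for l in range(cur, a):
                    out[g, l] = haplotypes[p, h, l]
                if a > cur:
                    cur = a
                h = 1 - h
            for l in range(cur, hi):
                out[g, l] = haplotypes[p, h, l]
            k += n_xo
    return out


def draw_gametes(haplotypes, parent_idx, chr_start, chr_end, locus_pos,
                 morgans, rng, out=None):
    """Sample one gamete per entry of ``parent_idx``.

    Parameters
    ----------
    haplotypes : int8 array, shape (n_parents, 2, L)
    parent_idx : int64 array, shape (G,)
    chr_start, chr_end : int64 arrays, shape (C,)
    locus_pos : float64 array, shape (L,)
        Within-chromosome genetic positions in Morgans, sorted per
        chromosome.
    morgans : float64 array, shape (C,)
        Genetic length of each chromosome.
    rng : numpy.random.Generator

    Returns
    -------
    int8 array, shape (G, L)
    """
    parent_idx = np.ascontiguousarray(parent_idx, dtype=np.int64)
    n_gametes = parent_idx.shape[0]
    n_chrom = chr_start.shape[0]
    start_hap = rng.integers(0, 2, size=(n_gametes, n_chrom), dtype=np.int8)
    xo_counts = rng.poisson(morgans, size=(n_gametes, n_chrom)).astype(np.int64)
    # positions uniform on each chromosome's genetic map
    xo_pos = (rng.random(int(xo_counts.sum()))
              * np.repeat(np.broadcast_to(morgans, xo_counts.shape).ravel(),
                          xo_counts.ravel()))
    if out is None:
        out = np.empty((n_gametes, haplotypes.shape[2]), dtype=np.int8)
    _build_gametes(haplotypes, parent_idx, start_hap, xo_counts, xo_pos,
                   chr_start, chr_end, locus_pos, out)
    return out
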