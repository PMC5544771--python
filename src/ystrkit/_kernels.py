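"""Numba-compiled hot loops for the coalescent + GSM simulator.

These kernels use numpy's legacy RNG seeded inside the jitted function, so a
given seed is bit-reproducible. Public modules wrap them with validated,
documented APIs; nothing here is part of the public surface.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sim_genealogy(n, is_growth, Na, Nc, Tstart, seed):  # pragma: no cover - jitted
    """Simulate a haploid coalescent genealogy.

    Backward in time the population size is Nc at present; under growth it
    shrinks exponentially to Na at Tstart and stays Na earlier. Returns
    (parent, times) arrays over 2n-1 nodes: tips are 0..n-1 at time 0,
    internal nodes appended in coalescence order, root parent = -1.
    """
    np.random.seed(seed)
    m = 2 * n - 1
    parent = np.full(m, -1, dtype=np.int64)
    times = np.zeros(m, dtype=np.float64)
    active = np.arange(n, dtype=np.int64)
    k = n
    t = 0.0
    nxt = n
    if is_growth and Nc != Na:
        r = np.log(Nc / Na) / Tstart
    else:
        r = 0.0
    while k > 1:
        pairs = 0.5 * k * (k - 1)
        e = np.random.exponential(1.0)
        if is_growth and r != 0.0 and t < Tstart:
            # integrated coalescent intensity under N(s) = Nc * exp(-r s)
            used_to_tstart = pairs * (np.exp(r * Tstart) - np.exp(r * t)) / (r * Nc)
            if e <= used_to_tstart:
                t = np.log(np.exp(r * t) + e * r * Nc / pairs) / r
            else:
                t = Tstart + (e - used_to_tstart) * Na / pairs
        else:
            size = Na if (is_growth and t >= Tstart) else (Na if is_growth else Nc)
            # constant model stores its single size in both Na and Nc
            t = t + np.random.exponential(size / pairs)
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        a = active[i]
        b = active[j]
        parent[a] = nxt
        parent[b] = nxt
        times[nxt] = t
        lo = min(i, j)
        hi = max(i, j)
        active[lo] = nxt
        active[hi] = active[k - 1]
        k -= 1
        nxt += 1
    return parent, times


@njit(cache=True)
def drop_mutations(parent, times, n_tips, rates, p_geom, ancestral, seed):  # pragma: no cover - jitted
    """Drop GSM mutations on a genealogy and return tip haplotypes.

    Mutations per locus per branch are Poisson(rate * length); each adds a
    signed geometric step (magnitude >= 1). A step that would push the
    repeat count below 1 is applied upward instead (reflection at 1).
    Returns (tip_alleles, n_events, sum_abs_steps) for instrumentation.
    """
    np.random.seed(seed)
    m = parent.shape[0]
    n_loci = rates.shape[0]
    alleles = np.empty((m, n_loci), dtype=np.int64)
    for j in range(n_loci):
        alleles[m - 1, j] = ancestral[j]
    n_events = 0
    sum_abs = 0
    for node in range(m - 2, -1, -1):
        par = parent[node]
        blen = times[par] - times[node]
        for j in range(n_loci):
            allele = alleles[par, j]
            n_mut = np.random.poisson(rates[j] * blen)
            for _ in range(n_mut):
                if p_geom <= 0.0:
                    step = 1
                else:
                    step = np.random.geometric(1.0 - p_geom)
                if np.random.random() < 0.5:
                    step = -step
                if allele + step < 1:
                    step = -step
                allele += step
                n_events += 1
                sum_abs += abs(step)
            alleles[node, j] = allele
    return alleles[:n_tips], n_events, sum_abs


@njit(cache=True)
def sample_steps(p_geom, size, seed):  # pragma: no cover - jitted
    """Draw GSM step magnitudes (>= 1) for distribution checks."""
    np.random.seed(seed)
    out = np.empty(size, dtype=np.int64)
    for i in range(size):
        if p_geom <= 0.0:
            out[i] = 1
        else:
            out[i] = np.random.geometric(1.0 - p_geom)
    return out
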