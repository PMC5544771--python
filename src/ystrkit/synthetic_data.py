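"""Coalescent + generalized stepwise mutation (GSM) simulator.

Generates Y-STR haplotype tables with known ground truth: a haploid
coalescent genealogy under constant-size or exponential-growth demography,
GSM-mutated repeat counts descending from a common ancestor, multi-population
labels, and simulated partial SNP typing. This module is both the engine
behind the ABC reference table and the test fixture factory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .haplotype_io import (
    HaplogroupTree,
    MutationRateTable,
    StrHaplotypeTable,
)

__all__ = [
    "DemographicModel",
    "GsmModel",
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_study",
]

_MAX_SEED = 2**31 - 1


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_MAX_SEED))


@dataclass(frozen=True)
class DemographicModel:
    """Haploid demography: constant size, or exponential growth.

    Backward in time the growth model has size ``N(t) = Nc * exp(-r t)`` for
    ``t`` in ``[0, Tstart]`` with ``r = ln(Nc/Na)/Tstart``, and ``Na`` earlier.
    A constant model stores its single size as ``Na == Nc``.
    """

    kind: str
    Na: float
    Nc: float
    Tstart: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "growth"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.Na <= 0 or self.Nc <= 0:
            raise ValueError("population sizes must be positive")
        if self.kind == "constant" and self.Na != self.Nc:
            raise ValueError("constant model requires Na == Nc")
        if self.kind == "growth":
            if self.Tstart <= 0:
                raise ValueError("growth model requires Tstart > 0")
            if not self.Na < self.Nc:
                raise ValueError("growth model requires Na < Nc")

    @classmethod
    def constant(cls, N: float) -> "DemographicModel":
        return cls("constant", N, N)

    @classmethod
    def growth(cls, Na: float, Nc: float, Tstart: float) -> "DemographicModel":
        return cls("growth", Na, Nc, Tstart)

    def size_at(self, t: float) -> float:
        """Population size at backward time ``t`` (generations)."""
        if self.kind == "constant":
            return self.Nc
        if t >= self.Tstart:
            return self.Na
        r = np.log(self.Nc / self.Na) / self.Tstart
        return self.Nc * np.exp(-r * t)


@dataclass(frozen=True)
class GsmModel:
    """Generalized stepwise mutation: geometric step magnitude, random sign.

    ``P(s) = (1 - p_geom) * p_geom**(s-1)`` for s >= 1; ``p_geom = 0``
    degenerates to the single-step model.
    """

    p_geom: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_geom <= 0.8:
            raise ValueError("p_geom must lie in [0, 0.8]")

    def sample_steps(self, size: int, rng_seed: int) -> np.ndarray:
        """Draw ``size`` step magnitudes (for distribution checks)."""
        return _kernels.sample_steps(self.p_geom, size, rng_seed % _MAX_SEED)


class Genealogy:
    """Rooted ultrametric genealogy over ``n`` sampled lineages.

    Nodes ``0..n-1`` are tips at time 0; internal nodes follow in
    coalescence order, so every parent index exceeds its children's. Times
    are in generations before present; the root's parent is -1.
    """

    def __init__(self, parent: np.ndarray, times: np.ndarray, n: int):
        parent = np.asarray(parent, dtype=np.int64)
        times = np.asarray(times, dtype=float)
        if parent.shape != times.shape:
            raise ValueError("parent/times shape mismatch")
        if np.count_nonzero(parent < 0) != 1:
            raise ValueError("genealogy must have exactly one root")
        self.parent = parent
        self.times = times
        self.n = int(n)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    @property
    def total_branch_length(self) -> float:
        mask = self.parent >= 0
        return float(np.sum(self.times[self.parent[mask]] - self.times[mask]))

    def rescaled(self, root_age: float) -> "Genealogy":
        """Linearly rescale node times so the root sits at ``root_age``.

        Fixture-mode only: pins the true age exactly at the cost of the
        coalescent variance in the root time.
        """
        if self.tmrca <= 0:
            raise ValueError("degenerate genealogy")
        return Genealogy(self.parent, self.times * (root_age / self.tmrca), self.n)

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                out[par].append(node)
        return out

    def tips_below(self) -> list[set[int]]:
        """Tip set under each node (tips map to singletons)."""
        sets: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for tip in range(self.n):
            sets[tip] = {tip}
        for node in range(self.n_nodes):  # children precede parents
            par = self.parent[node]
            if par >= 0:
                sets[par] |= sets[node]
        return sets

    @classmethod
    def star(cls, n: int, age: float) -> "Genealogy":
        """Star genealogy: all tips coalesce at once at ``age``."""
        parent = np.full(n + 1, n, dtype=np.int64)
        parent[n] = -1
        times = np.zeros(n + 1)
        times[n] = age
        return cls(parent, times, n)


def simulate_genealogy(n: int, model: DemographicModel, rng_seed: int) -> Genealogy:
    """Simulate a coalescent genealogy of ``n`` lineages under ``model``.

    The pairwise coalescence rate at backward time t is C(k,2)/N(t) for k
    extant lineages.
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    parent, times = _kernels.sim_genealogy(
        int(n),
        model.kind == "growth",
        float(model.Na),
        float(model.Nc),
        float(model.Tstart) if model.Tstart else 1.0,
        int(rng_seed) % _MAX_SEED,
    )
    return Genealogy(parent, times, n)


def drop_mutations(
    tree: Genealogy,
    rates: MutationRateTable,
    gsm: GsmModel,
    ancestral: np.ndarray,
    rng_seed: int,
    *,
    return_counts: bool = False,
):
    """Mutate ``ancestral`` down ``tree`` and return the tip haplotype table.

    Mutations per locus per branch are Poisson(rate × branch length); each
    adds a signed GSM step, reflecting at repeat count 1. With
    ``return_counts`` also returns (number of mutation events, summed
    absolute step size) for instrumentation.
    """
    ancestral = np.asarray(ancestral, dtype=np.int64)
    if ancestral.shape != (len(rates.loci),):
        raise ValueError("ancestral haplotype length must match rate table")
    if (ancestral < 1).any():
        raise ValueError("ancestral repeat counts must be >= 1")
    tips, n_events, sum_abs = _kernels.drop_mutations(
        tree.parent,
        tree.times,
        tree.n,
        rates.to_array(),
        float(gsm.p_geom),
        ancestral,
        int(rng_seed) % _MAX_SEED,
    )
    frame = pd.DataFrame(tips, columns=list(rates.loci))
    frame.insert(0, "sample_id", [f"sim{i:05d}" for i in range(tree.n)])
    frame.insert(1, "population", "sim")
    frame.insert(2, "haplogroup", None)
    table = StrHaplotypeTable(frame, normalized=True)
    if return_counts:
        return table, int(n_events), int(sum_abs)
    return table


def simulate_alleles(
    n: int,
    model: DemographicModel,
    rates: np.ndarray,
    p_geom: float,
    ancestral_allele: int,
    rng_seed_pair: tuple[int, int],
) -> np.ndarray:
    """Fast path for ABC: genealogy + mutations, returning a raw allele matrix."""
    parent, times = _kernels.sim_genealogy(
        int(n),
        model.kind == "growth",
        float(model.Na),
        float(model.Nc),
        float(model.Tstart) if model.Tstart else 1.0,
        rng_seed_pair[0] % _MAX_SEED,
    )
    ancestral = np.full(len(rates), int(ancestral_allele), dtype=np.int64)
    tips, _, _ = _kernels.drop_mutations(
        parent, times, int(n), np.asarray(rates, dtype=float), float(p_geom),
        ancestral, rng_seed_pair[1] % _MAX_SEED,
    )
    return tips


def _paint_haplogroups(
    genealogy: Genealogy,
    tree: HaplogroupTree,
    rng: np.random.Generator,
) -> list[str]:
    """Assign a terminal haplogroup state to every tip.

    The SNP-tree root is mapped to the genealogy root; each child SNP is
    painted onto a random internal clade nested inside its parent's clade,
    with sibling SNPs on disjoint clades. Tips in no child clade keep the
    parent's paragroup state. A child SNP may end up with zero carriers if
    no disjoint clade is available.
    """
    tipsets = genealogy.tips_below()
    internal = [v for v in range(genealogy.n, genealogy.n_nodes)]
    labels = [tree.terminal_state(tree.root)] * genealogy.n

    def assign(snp: str, gnode: int) -> None:
        state = tree.terminal_state(snp)
        for tip in tipsets[gnode]:
            labels[tip] = state
        taken: list[int] = []
        children = tree.children(snp)
        rng.shuffle(children)
        candidates = [v for v in internal
                      if v != gnode and tipsets[v] < tipsets[gnode]]
        for child in children:
            options = [v for v in candidates
                       if all(tipsets[v].isdisjoint(tipsets[w]) for w in taken)]
            if not options:
                continue
            pick = options[rng.integers(len(options))]
            taken.append(pick)
            assign(child, pick)

    assign(tree.root, genealogy.root)
    return labels


def simulate_study(
    n_per_pop: dict[str, int],
    model: DemographicModel,
    rates: MutationRateTable,
    gsm: GsmModel,
    tree: HaplogroupTree,
    true_age_generations: float,
    missing_rates: dict[str, float] | None = None,
    rng_seed: int = 0,
    ancestral: np.ndarray | None = None,
) -> StrHaplotypeTable:
    """Generate a full multi-population study table with known ground truth.

    One shared genealogy is simulated and linearly rescaled so the root sits
    exactly at ``true_age_generations``; terminal haplogroup labels are
    painted onto nested clades; for each partial code in ``missing_rates``
    the stated fraction of compatible individuals has its label degraded to
    that code.
    """
    missing_rates = missing_rates or {}
    for code, frac in missing_rates.items():
        if code not in tree.partial_codes:
            raise ValueError(f"unknown partial code {code!r}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for {code!r} outside [0, 1]")
    n_total = int(sum(n_per_pop.values()))
    if n_total < 2:
        raise ValueError("need at least 2 individuals in total")
    rng = np.random.default_rng(rng_seed)
    genealogy = simulate_genealogy(n_total, model, _spawn_seed(rng))
    genealogy = genealogy.rescaled(true_age_generations)
    if ancestral is None:
        ancestral = np.full(len(rates.loci), 15, dtype=np.int64)
    table = drop_mutations(genealogy, rates, gsm, ancestral, _spawn_seed(rng))

    labels = _paint_haplogroups(genealogy, tree, rng)
    for code, frac in missing_rates.items():
        compat = set(tree.partial_codes[code])
        for i in range(n_total):
            if labels[i] in compat and rng.random() < frac:
                labels[i] = code

    populations = np.repeat(
        [p for p in n_per_pop], [n_per_pop[p] for p in n_per_pop]
    )
    rng.shuffle(populations)
    frame = table.frame.copy()
    frame["population"] = populations
    frame["haplogroup"] = labels
    return StrHaplotypeTable(frame, normalized=True)
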