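"""Haplogroup age estimation from STR variation with the weighted rho statistic.

The weighted statistic rescales each locus's allelic distance to the median
haplotype by the ratio of the average to the locus-specific mutation rate, so
slow and fast loci contribute on a common time scale:

    rho_w = (1/N) * sum_i n_i * d_i,   d_i = sum_j |X_ji - X_jm| * mu_bar/mu_j

with standard deviation (1/N) * sqrt(sum_i n_i^2 * d_i^2). Multiplying by a
years-per-mutation rate converts rho to an age in years. An unweighted
variant operates on per-individual derived-mutation counts from whole-Y
sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .haplotype_io import (
    MutationRateTable,
    StrHaplotypeTable,
    collapse_haplotypes,
)

__all__ = [
    "AgeEstimate",
    "YearsPerMutation",
    "median_haplotype",
    "rho_weighted",
    "years_per_mutation_str",
    "years_per_mutation_sequence",
    "estimate_age",
    "rho_unweighted_counts",
    "diversity_stats",
]

Collapsed = Sequence[tuple[tuple[int, ...], int]]


@dataclass(frozen=True)
class AgeEstimate:
    rho_w: float
    sd_rho_w: float
    age_years: float
    sd_years: float
    ci95: tuple[float, float]
    n_used: int
    n_outliers: int = 0

    def __post_init__(self) -> None:
        assert self.rho_w >= 0 and self.sd_rho_w >= 0
        assert (self.age_years == 0) == (self.rho_w == 0)


@dataclass(frozen=True)
class YearsPerMutation:
    """Years per mutation for a whole marker system."""

    value: float
    provenance: str = "str_derived"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("years-per-mutation must be positive")


def _as_collapsed(haps) -> Collapsed:
    if isinstance(haps, StrHaplotypeTable):
        return collapse_haplotypes(haps)
    return list(haps)


def median_haplotype(haps: Collapsed | StrHaplotypeTable) -> np.ndarray:
    """Per-locus median allele over all chromosomes (counting multiplicity).

    Ties for an even number of chromosomes break toward the lower allele;
    this is a documented convention, isolated here so the alternative is a
    one-line change.
    """
    collapsed = _as_collapsed(haps)
    if not collapsed:
        raise ValueError("no haplotypes")
    vectors = np.array([v for v, _ in collapsed], dtype=np.int64)
    counts = np.array([n for _, n in collapsed], dtype=np.int64)
    n_total = int(counts.sum())
    lower_idx = (n_total - 1) // 2  # lower median position
    out = np.empty(vectors.shape[1], dtype=np.int64)
    for j in range(vectors.shape[1]):
        order = np.argsort(vectors[:, j], kind="stable")
        cum = np.cumsum(counts[order])
        out[j] = vectors[order, j][np.searchsorted(cum, lower_idx + 1)]
    return out


def _weighted_distances(
    vectors: np.ndarray, median: np.ndarray, rates: MutationRateTable,
    loci: Sequence[str],
) -> np.ndarray:
    weights = rates.mean_rate / rates.to_array(loci)
    return np.abs(vectors - median) @ weights


def rho_weighted(
    haps: Collapsed | StrHaplotypeTable,
    rates: MutationRateTable,
    *,
    loci: Sequence[str] | None = None,
    literal_sd: bool = False,
) -> tuple[float, float]:
    """Weighted rho and its standard deviation.

    ``literal_sd=True`` reproduces the typographically ambiguous printed
    form in which the per-haplotype distance enters the radical unsquared;
    the default squares it, which reduces to the classic rho standard error
    for unit counts.
    """
    collapsed = _as_collapsed(haps)
    if isinstance(haps, StrHaplotypeTable):
        loci = haps.loci
    if loci is None:
        loci = rates.loci
    if len(loci) != len(collapsed[0][0]):
        raise ValueError("locus list does not match haplotype length")
    if set(loci) - set(rates.loci):
        raise ValueError("haplotype loci missing from rate table")
    vectors = np.array([v for v, _ in collapsed], dtype=np.int64)
    counts = np.array([n for _, n in collapsed], dtype=float)
    n_total = counts.sum()
    d = _weighted_distances(vectors, median_haplotype(collapsed), rates, loci)
    rho = float(np.sum(counts * d) / n_total)
    inner = counts**2 * (d if literal_sd else d**2)
    sd = float(np.sqrt(np.sum(inner)) / n_total)
    return rho, sd


def years_per_mutation_str(rates: MutationRateTable) -> YearsPerMutation:
    """Years per mutation of the whole STR system.

    The reciprocal of the summed per-locus rate converted to years: one
    mutation anywhere in the haplotype every ``generation_time / sum(mu_j)``
    years, by analogy with the sequence-based constant.
    """
    total = rates.total_rate
    if total <= 0:
        raise ValueError("total mutation rate is zero")
    return YearsPerMutation(rates.generation_time / total, "str_derived")


def years_per_mutation_sequence(
    rate_per_site_year: float, callable_bp: float
) -> YearsPerMutation:
    """Years per mutation for whole-chromosome sequence data."""
    if rate_per_site_year <= 0 or callable_bp <= 0:
        raise ValueError("rate and callable length must be positive")
    return YearsPerMutation(1.0 / (rate_per_site_year * callable_bp),
                            "sequence_constant")


def _make_estimate(rho: float, sd: float, ypm: YearsPerMutation,
                   n_used: int, n_outliers: int) -> AgeEstimate:
    age = rho * ypm.value
    sd_years = sd * ypm.value
    return AgeEstimate(
        rho_w=rho, sd_rho_w=sd, age_years=age, sd_years=sd_years,
        ci95=(age - 1.96 * sd_years, age + 1.96 * sd_years),
        n_used=n_used, n_outliers=n_outliers,
    )


def estimate_age(
    haps: Collapsed | StrHaplotypeTable,
    rates: MutationRateTable,
    ypm: YearsPerMutation | None = None,
    outlier_policy: str = "none",
    *,
    mad_k: float = 5.0,
    literal_sd: bool = False,
) -> AgeEstimate:
    """Estimate a haplogroup age in years from STR variation.

    ``outlier_policy="mad"`` removes chromosomes whose weighted distance to
    the median haplotype exceeds median + ``mad_k``·MAD, then recomputes the
    statistic on the retained set.
    """
    if ypm is None:
        ypm = years_per_mutation_str(rates)
    loci = haps.loci if isinstance(haps, StrHaplotypeTable) else rates.loci
    collapsed = _as_collapsed(haps)
    n_total = sum(n for _, n in collapsed)
    if n_total < 2:
        raise ValueError("need at least 2 chromosomes")
    n_outliers = 0
    if outlier_policy == "mad":
        vectors = np.array([v for v, _ in collapsed], dtype=np.int64)
        counts = np.array([n for _, n in collapsed], dtype=np.int64)
        d = _weighted_distances(vectors, median_haplotype(collapsed), rates, loci)
        expanded = np.repeat(d, counts)
        med = np.median(expanded)
        mad = np.median(np.abs(expanded - med))
        if mad == 0:  # common when most chromosomes sit on the median
            mad = np.mean(np.abs(expanded - med))
        keep = d <= med + mad_k * mad
        n_outliers = int(np.sum(counts[~keep]))
        collapsed = [(tuple(v), int(n)) for v, n, k in
                     zip(vectors, counts, keep) if k]
        if not collapsed or sum(n for _, n in collapsed) < 2:
            raise ValueError("outlier removal left fewer than 2 chromosomes")
    elif outlier_policy != "none":
        raise ValueError(f"unknown outlier policy {outlier_policy!r}")
    rho, sd = rho_weighted(collapsed, rates, loci=loci, literal_sd=literal_sd)
    return _make_estimate(rho, sd, ypm, n_total - n_outliers, n_outliers)


def rho_unweighted_counts(
    derived_counts: Sequence[int], ypm: YearsPerMutation
) -> AgeEstimate:
    """Unweighted rho from per-individual derived-mutation counts.

    rho is the mean count; its standard deviation follows the Poisson-style
    convention sqrt(sum of counts)/N.
    """
    counts = np.asarray(derived_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no counts supplied")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rho = float(counts.mean())
    sd = float(np.sqrt(counts.sum()) / counts.size)
    return _make_estimate(rho, sd, ypm, counts.size, 0)


def diversity_stats(table: StrHaplotypeTable, by: str = "population") -> dict:
    """Per-group diversity report.

    For each group (plus an ``"All"`` pool): number of distinct haplotypes
    k, unbiased haplotype diversity Dhap, per-locus allele variance with its
    mean and across-locus sd, and the distribution of pairwise L1 distances
    between chromosomes.
    """
    if not table.normalized:
        raise ValueError("normalize the table before computing diversity")
    groups: dict = {}

    def one(sub: StrHaplotypeTable) -> dict:
        collapsed = collapse_haplotypes(sub)
        counts = np.array([n for _, n in collapsed], dtype=float)
        vectors = np.array([v for v, _ in collapsed], dtype=np.int64)
        n = counts.sum()
        report: dict = {"N": int(n), "k": len(collapsed)}
        if n >= 2:
            freqs = counts / n
            report["Dhap"] = float(n / (n - 1) * (1 - np.sum(freqs**2)))
        else:
            report["Dhap"] = None
        expanded = np.repeat(vectors, counts.astype(int), axis=0)
        per_locus_var = expanded.var(axis=0, ddof=1) if n >= 2 else \
            np.zeros(vectors.shape[1])
        report["var_mean"] = float(per_locus_var.mean())
        report["var_sd"] = float(per_locus_var.std(ddof=1)) \
            if vectors.shape[1] >= 2 else 0.0
        dist: Counter = Counter()
        for a in range(len(collapsed)):
            na = counts[a]
            if na >= 2:
                dist[0] += int(na * (na - 1) // 2)
            for b in range(a + 1, len(collapsed)):
                delta = int(np.abs(vectors[a] - vectors[b]).sum())
                dist[delta] += int(na * counts[b])
        report["pairwise_distances"] = dict(sorted(dist.items()))
        return report

    groups["All"] = one(table)
    for key, sub in table.groupby([by]):
        name = key[0] if isinstance(key, tuple) else key
        groups[str(name)] = one(sub)
    return groups
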