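"""Subhaplogroup frequency estimation with partially typed individuals.

Individuals carrying only a partial SNP typing code contribute fractional
counts to the terminal states compatible with their code, proportional to
the fully typed relative frequencies of those states within the same
population (falling back to pooled proportions, then to a uniform split,
when the relevant fully typed counts are zero). A single proportional pass
is performed — no EM iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .haplotype_io import NON_CLADE, HaplogroupTree, StrHaplotypeTable

logger = logging.getLogger(__name__)

__all__ = ["FrequencyEstimate", "allocate_partial", "frequency_table"]


@dataclass
class FrequencyEstimate:
    """Effective (possibly fractional) counts per terminal state for one population."""

    population: str
    counts: dict[str, float]
    n_full: int
    n_partial: int

    @property
    def n(self) -> int:
        return self.n_full + self.n_partial

    @property
    def frequencies(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError(f"population {self.population!r} is empty")
        return {s: c / total for s, c in self.counts.items()}


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, StrHaplotypeTable):
        return records.frame[["population", "haplogroup"]]
    frame = pd.DataFrame(records)
    if not {"population", "haplogroup"} <= set(frame.columns):
        raise ValueError("records need 'population' and 'haplogroup' columns")
    return frame


def allocate_partial(records, tree: HaplogroupTree) -> list[FrequencyEstimate]:
    """Allocate partially typed individuals over compatible terminal states.

    ``records`` is a StrHaplotypeTable or a frame with ``population`` and
    ``haplogroup`` columns; haplogroup values must be terminal states of
    ``tree``, the residual non-clade state, or partial codes declared by the
    tree. Total effective count is conserved exactly.
    """
    frame = _records_frame(records)
    universe = tree.terminal_states() + [NON_CLADE]
    known = set(universe) | set(tree.partial_codes)
    labels = frame["haplogroup"]
    if labels.isna().any():
        raise ValueError("records with missing haplogroup labels")
    unknown = sorted(set(labels) - known)
    if unknown:
        raise ValueError(f"unknown haplogroup codes: {unknown}")
    if frame.empty:
        raise ValueError("no records")

    full_mask = labels.isin(universe)
    pooled = labels[full_mask].value_counts().to_dict()

    estimates = []
    for pop, sub in frame.groupby("population", sort=True):
        counts = {s: 0.0 for s in universe}
        sub_labels = sub["haplogroup"]
        full = sub_labels[sub_labels.isin(universe)]
        partial = sub_labels[~sub_labels.isin(universe)]
        for state, n in full.value_counts().items():
            counts[state] += float(n)
        local = full.value_counts().to_dict()
        for code in partial:
            compat = tree.partial_codes[code]
            weights = [local.get(s, 0.0) for s in compat]
            if sum(weights) == 0:
                weights = [pooled.get(s, 0.0) for s in compat]
            if sum(weights) == 0:
                logger.warning(
                    "no fully typed reference for code %r in %r; uniform split",
                    code, pop,
                )
                weights = [1.0] * len(compat)
            total = sum(weights)
            for state, w in zip(compat, weights):
                counts[state] += w / total
        estimates.append(FrequencyEstimate(
            population=str(pop), counts=counts,
            n_full=int(len(full)), n_partial=int(len(partial)),
        ))
    return estimates


def frequency_table(
    estimates: list[FrequencyEstimate], tree: HaplogroupTree
) -> pd.DataFrame:
    """Long-format table of terminal and cumulative per-SNP frequencies.

    Each SNP row carries the frequency of its own terminal (paragroup)
    state and the cumulative frequency of all chromosomes derived for the
    SNP (its terminal state plus every state below it). The residual
    non-clade state appears with cumulative equal to terminal.
    """
    rows = []
    for est in estimates:
        freqs = est.frequencies
        for snp in tree.nodes:
            terminal = freqs.get(tree.terminal_state(snp), 0.0)
            cumulative = sum(freqs.get(s, 0.0) for s in tree.states_below(snp))
            rows.append({
                "population": est.population, "state": snp,
                "terminal_freq": terminal, "cumulative_freq": cumulative,
                "n_full": est.n_full, "n_partial": est.n_partial,
            })
        rows.append({
            "population": est.population, "state": NON_CLADE,
            "terminal_freq": freqs.get(NON_CLADE, 0.0),
            "cumulative_freq": freqs.get(NON_CLADE, 0.0),
            "n_full": est.n_full, "n_partial": est.n_partial,
        })
    return pd.DataFrame(rows)
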