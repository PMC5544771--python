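"""Readers, writers and domain types for Y-STR haplotype data.

Three data carriers live here:

* :class:`StrHaplotypeTable` — individuals × loci integer repeat counts with
  population and (sub)haplogroup labels;
* :class:`MutationRateTable` — per-locus mutation rates per generation;
* :class:`HaplogroupTree` — a nested SNP hierarchy with paragroup terminal
  states and partial-typing codes.

All downstream statistics assume integer repeat counts; rows carrying
microvariant alleles (e.g. ``13.2``) are rejected at load time.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

META_COLUMNS = ("sample_id", "population", "haplogroup")

#: Canonical Yfiler locus names as they appear in YHRD-style tables.
YFILER_LOCI = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "YGATAH4", "DYS385a", "DYS385b",
)

#: Residual terminal state for chromosomes outside the modelled clade.
NON_CLADE = "non-DF27"


class FormatError(ValueError):
    """Raised when an input file does not satisfy the expected layout."""


class EmptyInputError(ValueError):
    """Raised when a file yields zero valid rows."""


# ---------------------------------------------------------------------------
# Mutation rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRateTable:
    """Per-locus mutation rates (per generation) plus generation time.

    The mean rate is always recomputed from the listed rates rather than
    trusted from a file.
    """

    rates: dict[str, float]
    generation_time: float = 32.5

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError("rate table is empty")
        for locus, rate in self.rates.items():
            if not rate > 0:
                raise ValueError(f"non-positive rate for {locus}: {rate}")
        if not self.generation_time > 0:
            raise ValueError("generation_time must be positive")
        # keep locus order canonical (alphabetical)
        object.__setattr__(
            self, "rates", {k: float(self.rates[k]) for k in sorted(self.rates)}
        )

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.rates)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(list(self.rates.values())))

    @property
    def total_rate(self) -> float:
        return float(np.sum(list(self.rates.values())))

    def to_array(self, loci: Sequence[str] | None = None) -> np.ndarray:
        loci = self.loci if loci is None else tuple(loci)
        missing = [l for l in loci if l not in self.rates]
        if missing:
            raise KeyError(f"loci missing from rate table: {missing}")
        return np.array([self.rates[l] for l in loci], dtype=float)

    def subset(self, loci: Iterable[str]) -> "MutationRateTable":
        loci = tuple(loci)
        return MutationRateTable(
            {l: self.rates[l] for l in loci}, generation_time=self.generation_time
        )

    @classmethod
    def from_tsv(cls, path, generation_time: float = 32.5) -> "MutationRateTable":
        df = pd.read_csv(path, sep="\t")
        if not {"locus", "rate_per_generation"} <= set(df.columns):
            raise FormatError(
                "rate table must have columns 'locus' and 'rate_per_generation'"
            )
        return cls(
            dict(zip(df["locus"], df["rate_per_generation"].astype(float))),
            generation_time=generation_time,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"locus": list(self.rates), "rate_per_generation": list(self.rates.values())}
        ).to_csv(path, sep="\t", index=False)


def example_rates(generation_time: float = 32.5) -> MutationRateTable:
    """Frozen example Yfiler rate table shipped with the package.

    Replication against a specific YHRD snapshot requires the user's own
    table; this one only has realistic per-locus magnitudes.
    """
    ref = resources.files("ystrkit") / "data" / "yfiler_rates.tsv"
    with resources.as_file(ref) as path:
        return MutationRateTable.from_tsv(path, generation_time=generation_time)


# ---------------------------------------------------------------------------
# Haplotype table
# ---------------------------------------------------------------------------

class StrHaplotypeTable:
    """Validated table of Y-STR haplotypes.

    Parameters
    ----------
    data
        Frame with columns ``sample_id``, ``population``, ``haplogroup`` and
        one integer column per locus. Allele cells may be missing (``pd.NA``);
        rows with missing alleles are kept here but excluded from dating.
    normalized
        Whether Yfiler normalization (DYS385 removal, DYS389II adjustment)
        has already been applied.
    """

    def __init__(self, data: pd.DataFrame, *, normalized: bool = False,
                 n_rejected: int = 0):
        missing = [c for c in META_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"missing mandatory columns: {missing}")
        loci = sorted(c for c in data.columns if c not in META_COLUMNS)
        if not loci:
            raise FormatError("no locus columns present")
        dup = data["sample_id"][data["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicated sample_id: {sorted(set(dup))}")
        frame = data.loc[:, list(META_COLUMNS) + loci].reset_index(drop=True)
        for locus in loci:
            frame[locus] = frame[locus].astype("Int64")
            bad = frame[locus].dropna() < 1
            if bad.any():
                raise ValueError(f"non-positive allele at {locus}")
        frame["haplogroup"] = frame["haplogroup"].astype("object").where(
            frame["haplogroup"].notna() & (frame["haplogroup"].astype(str) != ""),
            None,
        )
        self._frame = frame
        self.loci: tuple[str, ...] = tuple(loci)
        self.normalized = bool(normalized)
        self.n_rejected = int(n_rejected)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def sample_id(self) -> pd.Series:
        return self._frame["sample_id"]

    @property
    def population(self) -> pd.Series:
        return self._frame["population"]

    @property
    def haplogroup(self) -> pd.Series:
        return self._frame["haplogroup"]

    def alleles(self) -> np.ndarray:
        """Complete-case allele matrix (rows with any missing allele dropped)."""
        sub = self._frame[list(self.loci)].dropna()
        return sub.to_numpy(dtype=np.int64)

    def complete_cases(self) -> "StrHaplotypeTable":
        """Drop rows with any missing allele (used before dating/ABC)."""
        mask = self._frame[list(self.loci)].notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("dropping %d rows with missing alleles", n_dropped)
        return StrHaplotypeTable(
            self._frame[mask], normalized=self.normalized, n_rejected=n_dropped
        )

    def select(self, mask) -> "StrHaplotypeTable":
        return StrHaplotypeTable(self._frame[np.asarray(mask)],
                                 normalized=self.normalized)

    def groupby(self, columns: Sequence[str]):
        for key, sub in self._frame.groupby(list(columns), dropna=False, sort=True):
            yield key, StrHaplotypeTable(sub, normalized=self.normalized)


def read_haplotypes(path, rate_table: MutationRateTable | None = None
                    ) -> StrHaplotypeTable:
    """Read a tab-separated haplotype table, rejecting invalid rows.

    Rows containing any non-integer (microvariant) allele are dropped and
    counted in ``table.n_rejected``. Empty cells are kept as missing. A
    leading ``# normalized=true`` comment (written by
    :func:`write_haplotypes`) marks an already-normalized table.
    """
    normalized = False
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        normalized = "normalized=true" in first.replace(" ", "").lower()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {missing}")
    loci = [c for c in df.columns if c not in META_COLUMNS]
    if not loci:
        raise FormatError("no locus columns in header")

    def to_int(cell):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
            return pd.NA
        try:
            value = float(cell)
        except ValueError:
            return "bad"
        if value != int(value):
            return "bad"
        return int(value)

    parsed = df[loci].map(to_int)
    bad_rows = (parsed == "bad").any(axis=1)
    n_rejected = int(bad_rows.sum())
    if n_rejected:
        logger.warning("rejected %d rows with non-integer alleles", n_rejected)
    keep = df[~bad_rows].copy()
    keep[loci] = parsed[~bad_rows]
    if keep.empty:
        raise EmptyInputError(f"no valid rows in {path}")
    table = StrHaplotypeTable(keep, normalized=normalized,
                              n_rejected=n_rejected)
    if rate_table is not None:
        extra = set(table.loci) - set(rate_table.loci) - {"DYS385a", "DYS385b"}
        if extra:
            logger.warning("loci without mutation rates: %s", sorted(extra))
    return table


def write_haplotypes(table: StrHaplotypeTable, path) -> None:
    frame = table.frame.copy()
    frame["haplogroup"] = frame["haplogroup"].fillna("")
    with open(path, "w") as fh:
        if table.normalized:
            fh.write("# normalized=true\n")
        frame.to_csv(fh, sep="\t", index=False)


def normalize_yfiler(table: StrHaplotypeTable) -> StrHaplotypeTable:
    """Apply Yfiler normalization: drop DYS385a/b, subtract DYS389I from DYS389II.

    Rows where DYS389II < DYS389I are rejected with a warning. Idempotent:
    an already-normalized table is returned unchanged.
    """
    if table.normalized:
        return table
    frame = table.frame.copy()
    n_rejected = 0
    if "DYS389I" in frame.columns and "DYS389II" in frame.columns:
        both = frame["DYS389I"].notna() & frame["DYS389II"].notna()
        # II == I would yield a zero repeat count, so it is rejected too
        bad = both & (frame["DYS389II"] <= frame["DYS389I"])
        n_rejected = int(bad.sum())
        if n_rejected:
            logger.warning("rejected %d rows with DYS389II < DYS389I", n_rejected)
        frame = frame[~bad].copy()
        frame["DYS389II"] = frame["DYS389II"] - frame["DYS389I"]
    frame = frame.drop(columns=[c for c in ("DYS385a", "DYS385b")
                                if c in frame.columns])
    if frame.empty:
        raise EmptyInputError("normalization rejected every row")
    return StrHaplotypeTable(frame, normalized=True, n_rejected=n_rejected)


def collapse_haplotypes(table: StrHaplotypeTable
                        ) -> list[tuple[tuple[int, ...], int]]:
    """Collapse identical complete haplotypes into (vector, count) pairs.

    Counts sum to the number of complete-case chromosomes; the number of
    entries is the number of distinct haplotypes k.
    """
    counts = Counter(tuple(int(a) for a in row) for row in table.alleles())
    return sorted(counts.items())


def expand_haplotypes(collapsed: Sequence[tuple[tuple[int, ...], int]]
                      ) -> np.ndarray:
    """Inverse of :func:`collapse_haplotypes` (row order canonical)."""
    rows = [vec for vec, n in collapsed for _ in range(n)]
    return np.array(rows, dtype=np.int64)


# ---------------------------------------------------------------------------
# SNP hierarchy
# ---------------------------------------------------------------------------

@dataclass
class HaplogroupTree:
    """Rooted SNP hierarchy with paragroup terminal states.

    ``parent`` maps each SNP name to its parent's name (root maps to None).
    Each internal node X implies a paragroup terminal state ``"X*"`` (derived
    for X but ancestral for all typed children); leaves are their own
    terminal state. ``partial_codes`` maps a partial-typing code to the set
    of terminal states compatible with it (may include the residual
    :data:`NON_CLADE` state).
    """

    parent: dict[str, str | None]
    partial_codes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        for node, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"unknown parent {par!r} of {node!r}")
        # reject cycles / non-arborescence
        for node in self.parent:
            seen = {node}
            cur = self.parent[node]
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle in tree")
                seen.add(cur)
                cur = self.parent[cur]
        universe = set(self.terminal_states()) | {NON_CLADE}
        for code, states in self.partial_codes.items():
            bad = set(states) - universe
            if bad:
                raise ValueError(f"partial code {code!r} names unknown states {bad}")
            if not states:
                raise ValueError(f"partial code {code!r} is empty")

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    def children(self, node: str) -> list[str]:
        return [n for n, p in self.parent.items() if p == node]

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def is_leaf(self, node: str) -> bool:
        return not self.children(node)

    def terminal_state(self, node: str) -> str:
        """Terminal state of a chromosome derived for ``node`` but no child."""
        return node if self.is_leaf(node) else f"{node}*"

    def terminal_states(self) -> list[str]:
        """All terminal states implied by the hierarchy, preorder."""
        out: list[str] = []

        def walk(node: str) -> None:
            out.append(self.terminal_state(node))
            for child in self.children(node):
                walk(child)

        walk(self.root)
        return out

    def states_below(self, node: str) -> list[str]:
        """Terminal states of chromosomes derived for ``node`` (cumulative)."""
        out = [self.terminal_state(node)]
        for child in self.children(node):
            out.extend(self.states_below(child))
        return out

    def node_of_state(self, state: str) -> str:
        return state[:-1] if state.endswith("*") else state

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "HaplogroupTree":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        parent = {entry["name"]: entry.get("parent") for entry in doc["nodes"]}
        return cls(parent, dict(doc.get("partial_codes", {})))

    def to_yaml(self, path) -> None:
        doc = {
            "nodes": [{"name": n, "parent": p} for n, p in self.parent.items()],
            "partial_codes": self.partial_codes,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_df27_tree() -> HaplogroupTree:
    """The DF27 subtree used throughout: DF27 → Z195 → {L176.2 → M167, Z220 → Z278 → M153}.

    Partial codes reflect the three typing failure patterns seen in input
    tables: R1b predicted from STRs only, P312 derived but untyped below,
    and Z195 derived but untested for L176.
    """
    parent = {
        "DF27": None,
        "Z195": "DF27",
        "L176.2": "Z195",
        "M167": "L176.2",
        "Z220": "Z195",
        "Z278": "Z220",
        "M153": "Z278",
    }
    tree = HaplogroupTree(parent)
    all_terminals = tree.terminal_states()
    tree.partial_codes = {
        "R1b_pred": all_terminals + [NON_CLADE],
        "P312_xZ195": ["DF27*", NON_CLADE],
        "Z195_xL176": ["Z195*", "L176.2*"],
    }
    return tree
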