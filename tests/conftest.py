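import numpy as np
import pandas as pd
import pytest

from ystrkit.haplotype_io import (
    MutationRateTable,
    StrHaplotypeTable,
    default_df27_tree,
    example_rates,
)


@pytest.fixture(scope="session")
def yfiler_rates() -> MutationRateTable:
    """Frozen 17-locus example rate table."""
    return example_rates()


@pytest.fixture(scope="session")
def rates15(yfiler_rates) -> MutationRateTable:
    """The 15 normalized loci (DYS385a/b excluded)."""
    return yfiler_rates.subset(
        l for l in yfiler_rates.loci if not l.startswith("DYS385")
    )


@pytest.fixture(scope="session")
def tree():
    return default_df27_tree()


@pytest.fixture
def two_locus_rates() -> MutationRateTable:
    return MutationRateTable({"L1": 0.002, "L2": 0.004})


def make_table(alleles, loci, populations=None, haplogroups=None,
               normalized=True) -> StrHaplotypeTable:
    alleles = np.asarray(alleles)
    n = alleles.shape[0]
    frame = pd.DataFrame(alleles, columns=list(loci))
    frame.insert(0, "sample_id", [f"s{i}" for i in range(n)])
    frame.insert(1, "population", populations if populations is not None else "pop")
    frame.insert(2, "haplogroup", haplogroups)
    return StrHaplotypeTable(frame, normalized=normalized)


@pytest.fixture
def table_factory():
    return make_table
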