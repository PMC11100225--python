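import numpy as np
import pandas as pd
import pytest

from rhizolink.tables_io import SampleMetadata, TaxonAbundanceTable


@pytest.fixture
def counts_table():
    """Small counts table: 4 taxa x 6 samples across 2 groups."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(4, 6)),
        index=[f"t{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(6)],
    )
    data.iloc[0, :] += 1  # taxon t0 present everywhere
    return TaxonAbundanceTable(data, kind="counts")


@pytest.fixture
def two_group_metadata():
    ids = [f"s{j}" for j in range(6)]
    return SampleMetadata(pd.Series(["A"] * 3 + ["B"] * 3, index=ids, name="group"))


def make_table(values, kind="counts", taxa=None, samples=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return TaxonAbundanceTable(
        pd.DataFrame(values, index=taxa, columns=samples), kind=kind
    )
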