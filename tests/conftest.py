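import numpy as np
import pandas as pd
import pytest

from coocnet.datatypes import AbundanceTable, TAXONOMY_COLUMNS


def make_table(counts, taxonomy=None, metadata=None, taxon_ids=None, sample_ids=None):
    """Build an AbundanceTable from a plain array with sensible defaults."""
    counts = np.asarray(counts, dtype=float)
    p, n = counts.shape
    taxon_ids = taxon_ids or [f"t{i}" for i in range(p)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    counts_df = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {
                "domain": "Bacteria",
                "class": "c0",
                "order": "o0",
                "family": "f0",
                "genus": [f"g{i}" for i in range(p)],
                "species": [f"sp{i}" for i in range(p)],
            },
            index=taxon_ids,
        )[list(TAXONOMY_COLUMNS)]
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "population": "LC",
                "biomass_g": np.nan,
                "batch": "b0",
                "run_group": sample_ids,
            },
            index=sample_ids,
        )
    return AbundanceTable(counts_df, taxonomy, metadata)


@pytest.fixture
def small_table():
    return make_table([[2.0, 0.0, 5.0], [1.0, 1.0, 1.0], [0.0, 4.0, 4.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
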