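import numpy as np
import pandas as pd
import pytest

from hillbeta import CountTable, make_random_table, make_structured_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def structured():
    """The eight-sample structured toy table (S0-S7)."""
    return make_structured_table()


@pytest.fixture
def random_table(rng):
    return make_random_table(n_taxa=20, n_samples=6, depth=300, rng=rng)


def table_from_dict(cols: dict[str, dict[str, int]], sequences=None) -> CountTable:
    """Build a CountTable from {sample: {taxon: count}} (absent taxa are 0)."""
    taxa = sorted({t for col in cols.values() for t in col})
    df = pd.DataFrame(
        {s: [col.get(t, 0) for t in taxa] for s, col in cols.items()}, index=taxa
    )
    return CountTable(df, sequences=sequences)
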