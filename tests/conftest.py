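import numpy as np
import pandas as pd
import pytest

from missbench.containers import Dataset, FeatureTable


def build_dataset(numeric, categorical=None, outcome=None, consequences=None):
    """Assemble a Dataset from plain dicts/arrays for compact test setup."""
    num = pd.DataFrame(numeric, dtype=float)
    num.index = pd.Index([f"v{i}" for i in range(len(num))], name="variant_id")
    cat = None
    if categorical is not None:
        cat = pd.DataFrame(categorical, index=num.index, dtype=object)
    n = len(num)
    out = pd.Series(outcome if outcome is not None else [i % 2 for i in range(n)], index=num.index)
    cons = pd.Series(
        consequences if consequences is not None else ["NON-SYNONYMOUS"] * n, index=num.index
    )
    return Dataset(FeatureTable(num, cat), out, cons)


def random_incomplete_frame(rng, n_rows=30, n_cols=6, missing_rate=0.2, prefix="f"):
    """A random numeric table with MCAR holes; every column keeps >= 1 observed
    value and every row the table needs stays usable downstream."""
    values = rng.normal(size=(n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < missing_rate
    for j in range(n_cols):  # keep at least two observed values per column
        observed = np.flatnonzero(~mask[:, j])
        if len(observed) < 2:
            mask[rng.choice(n_rows, size=2, replace=False), j] = False
    values[mask] = np.nan
    return pd.DataFrame(
        values,
        columns=[f"{prefix}{j}" for j in range(n_cols)],
        index=pd.Index([f"v{i}" for i in range(n_rows)], name="variant_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
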