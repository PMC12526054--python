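"""k-nearest-neighbor imputation over the complete-case reference set.

Only complete cases (rows with no missing value) are legal neighbors.
Distances are per-feature standardized Euclidean computed over the features
*observed* in the row being imputed; missing cells are filled with the
unweighted mean of the k nearest complete cases' values.  Distance ties are
broken by lower reference row index.  When k equals the number of complete
cases this reduces exactly to complete-case per-feature mean imputation — a
degenerate regime that real annotation tables, with their handful of
complete cases, sit very close to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import InsufficientCompleteCases

__all__ = ["fit_knn", "apply_knn"]


def fit_knn(df: pd.DataFrame, k: int) -> tuple[pd.DataFrame, pd.Series]:
    """Extract the complete-case reference set and per-feature scales."""
    if k < 1:
        raise ValueError("k must be >= 1")
    reference = df.dropna()
    if k > len(reference):
        raise InsufficientCompleteCases(
            f"k={k} exceeds the {len(reference)} complete cases in the training set"
        )
    scales = df.std(ddof=1)
    scales = scales.where((scales > 0) & scales.notna(), 1.0)
    return reference.copy(), scales


def apply_knn(
    df: pd.DataFrame, reference: pd.DataFrame, scales: pd.Series, k: int
) -> pd.DataFrame:
    """Fill each incomplete row from its k nearest complete reference cases.

    Rows are processed grouped by missingness pattern so each pattern costs
    one vectorised distance computation.
    """
    ref = reference.to_numpy()
    scale = scales.to_numpy()
    ref_scaled = ref / scale
    values = df.to_numpy().copy()
    mask = np.isnan(values)
    incomplete = np.flatnonzero(mask.any(axis=1))
    if incomplete.size:
        patterns = np.packbits(mask[incomplete], axis=1)
        _, inverse = np.unique(patterns, axis=0, return_inverse=True)
        for pat in np.unique(inverse):
            rows = incomplete[inverse == pat]
            miss = mask[rows[0]]
            obs = ~miss
            if obs.any():
                x = values[np.ix_(rows, np.flatnonzero(obs))] / scale[obs]
                d2 = ((x[:, None, :] - ref_scaled[None, :, obs]) ** 2).sum(axis=2)
            else:
                d2 = np.zeros((len(rows), len(ref)))  # nothing observed: all tie
            order = np.argsort(d2, axis=1, kind="stable")[:, :k]  # ties -> lower row index
            fills = ref[:, miss][order].mean(axis=1)
            values[np.ix_(rows, np.flatnonzero(miss))] = fills
    return pd.DataFrame(values, index=df.index, columns=df.columns)
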