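"""Aligned tabular containers for annotated genetic variants.

The unit of data flowing through every pipeline stage is a :class:`Dataset`:
a :class:`FeatureTable` (numeric and categorical annotation grids), a binary
pathogenicity outcome (1 = pathogenic / likely pathogenic), and a predicted
molecular-consequence label per variant, all aligned on one ordered, unique
variant index.

A single representation of "missing" is used throughout: ``NaN``.  Text
readers (:mod:`missbench.io`) normalise common markers (empty string, ``NA``,
``.``) to it on ingestion, so no sentinel-vs-NaN ambiguity can arise
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "Dataset",
    "missingness_mask",
    "missingness_by_consequence",
    "indicator_outcome_correlations",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(eq=False)
class FeatureTable:
    """Numeric and categorical feature grids sharing one variant index.

    Parameters
    ----------
    numeric
        Real-valued annotations, one column per feature, ``NaN`` = missing.
    categorical
        Category labels (object dtype), ``NaN`` = missing.  May be empty.
    """

    numeric: pd.DataFrame
    categorical: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.categorical is None:
            self.categorical = pd.DataFrame(index=self.numeric.index)
        _require(self.numeric.index.is_unique, "variant identifiers must be unique")
        _require(
            self.numeric.index.equals(self.categorical.index),
            "numeric and categorical grids must share the variant index",
        )
        overlap = set(self.numeric.columns) & set(self.categorical.columns)
        _require(not overlap, f"feature names appear in both grids: {sorted(overlap)}")
        self.numeric = self.numeric.astype(float)

    @property
    def variant_ids(self) -> pd.Index:
        return self.numeric.index

    @property
    def n_variants(self) -> int:
        return len(self.numeric)

    @property
    def feature_names(self) -> list[str]:
        return list(self.numeric.columns) + list(self.categorical.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.numeric.copy(), self.categorical.copy())

    def take(self, indexer) -> "FeatureTable":
        """Row subset by boolean mask or positional/label indexer."""
        return FeatureTable(self.numeric.loc[indexer], self.categorical.loc[indexer])


@dataclass(eq=False)
class Dataset:
    """A feature table with its outcome and consequence labels, row-aligned."""

    features: FeatureTable
    outcome: pd.Series
    consequences: pd.Series

    def __post_init__(self) -> None:
        idx = self.features.variant_ids
        _require(self.outcome.index.equals(idx), "outcome must align with features")
        _require(self.consequences.index.equals(idx), "consequences must align with features")
        values = set(pd.unique(self.outcome.dropna()))
        _require(values <= {0, 1}, f"outcome must be binary 0/1, got {values}")
        _require(not self.outcome.isna().any(), "outcome may not contain missing labels")
        _require(not self.consequences.isna().any(), "consequence labels may not be missing")
        self.outcome = self.outcome.astype(int)
        self.consequences = self.consequences.astype(str)

    @property
    def n_variants(self) -> int:
        return self.features.n_variants

    def copy(self) -> "Dataset":
        return Dataset(self.features.copy(), self.outcome.copy(), self.consequences.copy())

    def take(self, indexer) -> "Dataset":
        return Dataset(
            self.features.take(indexer),
            self.outcome.loc[indexer],
            self.consequences.loc[indexer],
        )


def missingness_mask(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Boolean grid, True where a cell is missing.

    Accepts a raw grid or a :class:`FeatureTable` (numeric and categorical
    grids concatenated column-wise, numeric first).  A pure query: repeated
    application to the same table yields identical masks.
    """
    if isinstance(table, FeatureTable):
        grid = pd.concat([table.numeric, table.categorical], axis=1)
    else:
        grid = table
    return grid.isna()


def missingness_by_consequence(
    ds: Dataset, classes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-(consequence class, feature) fraction of missing cells.

    Rows are consequence classes, columns features (original features only,
    numeric then categorical).  An empty class yields ``NaN`` entries — the
    "undefined" flag — never 0.
    """
    _require(ds.n_variants > 0, "dataset is empty")
    mask = missingness_mask(ds.features)
    if classes is None:
        classes = list(pd.unique(ds.consequences))
    out = pd.DataFrame(index=pd.Index(classes, name="consequence"), columns=mask.columns, dtype=float)
    for cls in classes:
        members = ds.consequences == cls
        n = int(members.sum())
        if n == 0:
            continue  # stays NaN: undefined, not zero
        out.loc[cls] = mask.loc[members.to_numpy()].sum(axis=0) / n
    return out


def indicator_outcome_correlations(ds: Dataset) -> pd.Series:
    """Pearson correlation of each feature's missingness indicator with the outcome.

    Features whose indicator is constant (never or always missing) are flagged
    ``NaN`` — undefined, not zero.  Raises if the outcome has a single class,
    since the correlation is then undefined for every feature.
    """
    y = ds.outcome.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    mask = missingness_mask(ds.features).to_numpy(dtype=float)
    out = pd.Series(np.nan, index=missingness_mask(ds.features).columns, dtype=float)
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    for j, name in enumerate(out.index):
        m = mask[:, j]
        mc = m - m.mean()
        m_ss = float(mc @ mc)
        if m_ss == 0.0:
            continue  # constant indicator: undefined flag
        out[name] = float(mc @ yc) / np.sqrt(m_ss * y_ss)
    return out
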