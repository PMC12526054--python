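"""Delimited-text reading and writing of variant feature tables.

A :class:`TableSchema` names the identifier, outcome and consequence columns,
lists which feature columns are categorical (everything else is numeric), and
defines the clinical-significance label vocabulary.  All common missing-value
markers are normalised to ``NaN`` on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Dataset, FeatureTable

__all__ = ["TableSchema", "read_raw_table", "read_dataset", "write_dataset"]

MISSING_TOKENS = ("", "NA", "NaN", "nan", ".", "NULL")


@dataclass(frozen=True)
class TableSchema:
    """Column layout and label vocabulary of a delimited variant table."""

    id_column: str = "variant_id"
    outcome_column: str = "clinical_significance"
    consequence_column: str = "consequence"
    categorical_columns: tuple[str, ...] = ()
    positive_labels: tuple[str, ...] = ("Pathogenic", "Likely_pathogenic")
    negative_labels: tuple[str, ...] = ("Benign", "Likely_benign")
    vus_labels: tuple[str, ...] = ("Uncertain_significance", "VUS")
    separator: str = ","


def read_raw_table(path: str | Path, schema: TableSchema = TableSchema()):
    """Read a delimited table into (features, raw outcome labels, consequences).

    Outcome labels are returned verbatim (they may include VUS); use
    :func:`missbench.preprocessing.encode_outcome_and_drop_vus` to obtain a
    binary :class:`~missbench.containers.Dataset`.
    """
    df = pd.read_csv(
        path,
        sep=schema.separator,
        na_values=list(MISSING_TOKENS),
        keep_default_na=True,
        dtype={schema.id_column: str},
    )
    for col in (schema.id_column, schema.outcome_column, schema.consequence_column):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} not found in {path}")
    df = df.set_index(schema.id_column)
    df.index.name = "variant_id"
    labels = df[schema.outcome_column].astype("object")
    consequences = df[schema.consequence_column].astype(str)
    feature_cols = [
        c for c in df.columns if c not in (schema.outcome_column, schema.consequence_column)
    ]
    cat_cols = [c for c in feature_cols if c in schema.categorical_columns]
    num_cols = [c for c in feature_cols if c not in schema.categorical_columns]
    numeric = df[num_cols].apply(pd.to_numeric)
    categorical = df[cat_cols].astype("object")
    return FeatureTable(numeric, categorical), labels, consequences


def read_dataset(path: str | Path, schema: TableSchema = TableSchema()) -> Dataset:
    """Read a table whose outcome labels map cleanly onto the binary classes.

    Positive/negative labels (and literal ``1``/``0``) are accepted; any other
    label, including VUS, is an error — route such tables through
    preprocessing instead.
    """
    features, labels, consequences = read_raw_table(path, schema)
    mapping: dict[object, int] = {"1": 1, "0": 0, 1: 1, 0: 0}
    mapping.update({lab: 1 for lab in schema.positive_labels})
    mapping.update({lab: 0 for lab in schema.negative_labels})
    unmapped = set(labels.unique()) - set(mapping)
    if unmapped:
        raise ValueError(f"unmapped outcome labels {sorted(map(str, unmapped))}")
    outcome = labels.map(mapping).astype(int)
    return Dataset(features, outcome, consequences)


def write_dataset(ds: Dataset, path: str | Path, schema: TableSchema = TableSchema()) -> None:
    """Write a dataset as CSV with ``NA`` marking missing cells."""
    out = pd.concat([ds.features.numeric, ds.features.categorical], axis=1)
    out[schema.outcome_column] = np.where(
        ds.outcome.to_numpy() == 1, schema.positive_labels[0], schema.negative_labels[0]
    )
    out[schema.consequence_column] = ds.consequences
    out.index.name = schema.id_column
    out.to_csv(path, sep=schema.separator, na_rep="NA")
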