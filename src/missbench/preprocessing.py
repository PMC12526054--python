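"""Static preprocessing and training-time feature filtering.

The fixed pipeline order is: a-priori default fills -> outcome encoding with
removal of variants of uncertain significance -> feature-vector
deduplication -> consequence-imbalance filtering -> categorical dummy
encoding -> train/test split.  Feature filtering (unique-value and
correlation rules) is deliberately deferred to training time because added
missingness can change its outcome; the fitted filter is then matched onto
the test set, followed by cross-set duplicate removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import Dataset, FeatureTable

__all__ = [
    "SplitSpec",
    "FeatureFilterRecord",
    "apply_apriori_defaults",
    "encode_outcome_and_drop_vus",
    "dedupe_feature_vectors",
    "filter_imbalanced_consequences",
    "encode_categoricals",
    "split",
    "fit_feature_filter",
    "apply_feature_filter",
    "remove_cross_set_duplicates",
]

logger = logging.getLogger(__name__)

POSITIVE_LABELS = ("Pathogenic", "Likely_pathogenic")
NEGATIVE_LABELS = ("Benign", "Likely_benign")
VUS_LABELS = ("Uncertain_significance", "VUS")


@dataclass(frozen=True)
class SplitSpec:
    """Seeded simple random train/test split."""

    train_fraction: float = 0.7
    seed: int = 0


@dataclass
class FeatureFilterRecord:
    """Audit trail of training-time feature filtering decisions."""

    dropped_low_unique: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str]] = field(default_factory=list)  # (kept, dropped)
    surviving_features: list[str] = field(default_factory=list)


def apply_apriori_defaults(
    ds: Dataset | FeatureTable, defaults: Mapping[str, float]
) -> Dataset | FeatureTable:
    """Fill listed numeric features with their a-priori default values.

    Used for features whose missingness *implies* the value (e.g. an absent
    population allele frequency implies frequency 0).  All other cells are
    untouched.
    """
    table = ds.features if isinstance(ds, Dataset) else ds
    unknown = set(defaults) - set(table.numeric.columns)
    if unknown:
        raise ValueError(f"defaults name unknown numeric features: {sorted(unknown)}")
    numeric = table.numeric.copy()
    for feat, value in defaults.items():
        numeric[feat] = numeric[feat].fillna(float(value))
    new_table = FeatureTable(numeric, table.categorical.copy())
    if isinstance(ds, Dataset):
        return Dataset(new_table, ds.outcome.copy(), ds.consequences.copy())
    return new_table


def encode_outcome_and_drop_vus(
    features: FeatureTable,
    labels: pd.Series,
    consequences: pd.Series,
    positive: Sequence[str] = POSITIVE_LABELS,
    negative: Sequence[str] = NEGATIVE_LABELS,
    vus: Sequence[str] = VUS_LABELS,
) -> Dataset:
    """Map clinical-significance labels to a binary outcome, dropping VUS rows."""
    mapping: dict[str, int] = {}
    mapping.update({lab: 1 for lab in positive})
    mapping.update({lab: 0 for lab in negative})
    known = set(mapping) | set(vus)
    unmapped = set(labels.unique()) - known
    if unmapped:
        raise ValueError(f"unmapped clinical-significance labels: {sorted(map(str, unmapped))}")
    keep = ~labels.isin(list(vus))
    n_vus = int((~keep).sum())
    if n_vus:
        logger.info("dropping %d variants of uncertain significance", n_vus)
    outcome = labels[keep].map(mapping).astype(int)
    return Dataset(features.take(keep.to_numpy()), outcome, consequences[keep])


def dedupe_feature_vectors(ds: Dataset) -> Dataset:
    """Keep one variant per equivalence class of identical full feature vectors.

    Missing cells compare equal to missing; numerics compare exactly.  The
    first occurrence in input order is kept.
    """
    grid = pd.concat([ds.features.numeric, ds.features.categorical], axis=1)
    keep = ~grid.duplicated(keep="first")
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d duplicated feature vectors", removed)
    return ds.take(keep.to_numpy())


def filter_imbalanced_consequences(ds: Dataset, threshold: float = 0.05) -> Dataset:
    """Drop consequence classes where either outcome class holds < threshold
    of that consequence's variants (strict <, so exactly-at-threshold survives)."""
    keep_classes = []
    for cls in pd.unique(ds.consequences):
        members = ds.consequences == cls
        pos_frac = float(ds.outcome[members].mean())
        if pos_frac >= threshold and (1.0 - pos_frac) >= threshold:
            keep_classes.append(cls)
        else:
            logger.info(
                "dropping consequence class %s (positive fraction %.3f)", cls, pos_frac
            )
    if not keep_classes:
        raise ValueError("imbalance filter removed every consequence class")
    keep = ds.consequences.isin(keep_classes)
    return ds.take(keep.to_numpy())


def encode_categoricals(ds: Dataset) -> Dataset:
    """Expand each categorical feature into binary indicators over its levels
    plus one extra indicator for the missing category.

    Every row activates exactly one indicator per original feature, so the
    resulting indicators carry no missing cells.
    """
    numeric = ds.features.numeric.copy()
    for feat in ds.features.categorical.columns:
        col = ds.features.categorical[feat]
        levels = sorted(col.dropna().unique())
        for level in levels:
            numeric[f"{feat}={level}"] = (col == level).astype(float)
        numeric[f"{feat}=MISSING"] = col.isna().astype(float)
    empty_cat = pd.DataFrame(index=ds.features.variant_ids)
    return Dataset(FeatureTable(numeric, empty_cat), ds.outcome.copy(), ds.consequences.copy())


def split(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Seeded simple random split; |train| = round(fraction * n)."""
    if not 0.0 < spec.train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = ds.n_variants
    n_train = int(round(spec.train_fraction * n))
    if n_train < 1 or n_train > n - 1:
        raise ValueError(f"cannot split {n} variants into non-empty subsets at fraction {spec.train_fraction}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_pos = np.sort(perm[:n_train])
    test_pos = np.sort(perm[n_train:])
    mask_train = np.zeros(n, dtype=bool)
    mask_train[train_pos] = True
    mask_test = np.zeros(n, dtype=bool)
    mask_test[test_pos] = True
    return ds.take(mask_train), ds.take(mask_test)


def fit_feature_filter(
    train: Dataset | pd.DataFrame,
    unique_threshold: float = 0.01,
    corr_threshold: float = 0.9,
    unique_denominator: str = "all",
) -> FeatureFilterRecord:
    """Fit the training-time feature filter on numeric features.

    First drops features whose count of distinct observed values divided by
    the row count (``unique_denominator="all"``) or by the observed count
    (``"observed"``) is strictly below ``unique_threshold``.  Then greedily
    scans surviving feature pairs in column order and, for each pair with
    |Pearson r| > ``corr_threshold`` over pairwise-complete rows, drops the
    later column.  Both rules exist to keep chained-equations design matrices
    non-singular.
    """
    df = train.features.numeric if isinstance(train, Dataset) else train
    n_rows = len(df)
    record = FeatureFilterRecord()
    survivors: list[str] = []
    for feat in df.columns:
        observed = df[feat].dropna()
        denom = n_rows if unique_denominator == "all" else max(len(observed), 1)
        if denom == 0 or observed.nunique() / denom < unique_threshold:
            record.dropped_low_unique.append(feat)
        else:
            survivors.append(feat)
    if survivors:
        corr = df[survivors].corr()  # pairwise-complete Pearson
        dropped: set[str] = set()
        for i, a in enumerate(survivors):
            if a in dropped:
                continue
            for b in survivors[i + 1 :]:
                if b in dropped:
                    continue
                r = corr.loc[a, b]
                if pd.notna(r) and abs(r) > corr_threshold:
                    dropped.add(b)
                    record.dropped_correlated.append((a, b))
        survivors = [f for f in survivors if f not in dropped]
    if not survivors:
        raise ValueError("feature filter dropped every feature")
    record.surviving_features = survivors
    return record


def apply_feature_filter(ds: Dataset, record: FeatureFilterRecord) -> Dataset:
    """Restrict a dataset to the filter's surviving features, same order."""
    missing = set(record.surviving_features) - set(ds.features.numeric.columns)
    if missing:
        raise ValueError(f"dataset lacks surviving features {sorted(missing)}")
    table = FeatureTable(
        ds.features.numeric[record.surviving_features], ds.features.categorical.copy()
    )
    return Dataset(table, ds.outcome.copy(), ds.consequences.copy())


def remove_cross_set_duplicates(train: Dataset, test: Dataset) -> Dataset:
    """Drop test rows whose feature vector duplicates a training row or an
    earlier test row (missing compares equal to missing)."""
    if list(train.features.numeric.columns) != list(test.features.numeric.columns):
        raise ValueError("train and test must share the post-filter feature set")
    train_grid = pd.concat([train.features.numeric, train.features.categorical], axis=1)
    test_grid = pd.concat([test.features.numeric, test.features.categorical], axis=1)
    combined = pd.concat([train_grid, test_grid], axis=0, ignore_index=True)
    dup = combined.duplicated(keep="first").to_numpy()[len(train_grid):]
    if dup.any():
        logger.info("removed %d duplicated test variants", int(dup.sum()))
    return test.take(~dup)
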