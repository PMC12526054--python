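"""Simple per-feature fills and missingness-indicator augmentation."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simple_fill_values", "indicator_pattern_columns", "apply_indicator_augmentation"]

INDICATOR_PREFIX = "missing_"


def simple_fill_values(method: str, df: pd.DataFrame) -> pd.Series:
    """Learned fill value per feature from observed values only.

    ``outlier`` fills with |max - min| * 10, an intentionally out-of-range
    constant; for a constant feature this degenerates to 0 (such features are
    normally removed upstream by the unique-value filter).
    """
    reducers = {
        "zero": lambda obs: 0.0,
        "mean": lambda obs: float(np.mean(obs)),
        "median": lambda obs: float(np.median(obs)),
        "minimum": lambda obs: float(np.min(obs)),
        "maximum": lambda obs: float(np.max(obs)),
        "outlier": lambda obs: abs(float(np.max(obs)) - float(np.min(obs))) * 10.0,
    }
    if method not in reducers:
        raise ValueError(f"not a simple method: {method}")
    reduce = reducers[method]
    return pd.Series(
        {col: reduce(df[col].dropna().to_numpy()) for col in df.columns}, dtype=float
    )


def indicator_pattern_columns(df: pd.DataFrame) -> list[str]:
    """Features whose missingness indicator is kept after deduplication.

    One indicator per *distinct* missingness pattern among features that have
    at least one missing cell; for identical indicator vectors only the
    first-named feature's indicator is kept (column order).
    """
    mask = df.isna()
    kept: list[str] = []
    seen: set[bytes] = set()
    for feat in df.columns:
        col = mask[feat].to_numpy()
        if not col.any():
            continue
        key = np.packbits(col).tobytes()
        if key in seen:
            continue
        seen.add(key)
        kept.append(feat)
    return kept


def apply_indicator_augmentation(df: pd.DataFrame, kept_columns: list[str]) -> pd.DataFrame:
    """Zero-fill all missing cells and append the kept binary indicators.

    Which indicator columns exist is learned from training data; their values
    reflect the missingness of the table being imputed.
    """
    out = df.fillna(0.0)
    for feat in kept_columns:
        out[INDICATOR_PREFIX + feat] = df[feat].isna().astype(float)
    return out
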