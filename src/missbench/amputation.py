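"""MCAR amputation: adding missing values to already-incomplete data.

The additional-missingness level is defined as a fraction of the *currently
observed* numeric cells: ``round(level * n_observed)`` cells are drawn
uniformly without replacement and set missing, with their original values
recorded for later RMSE evaluation.  Outcome, consequence and categorical
columns are never touched.  The overall observed missingness fraction after
amputation (original + additional) is reported alongside, since that is the
natural x-axis for missingness-response curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .containers import Dataset, FeatureTable
from .io import TableSchema, read_dataset, write_dataset

__all__ = [
    "AmputedDataset",
    "ampute_mcar",
    "generate_amputation_suite",
    "write_amputed",
    "read_amputed",
]


@dataclass(eq=False)
class AmputedDataset:
    """A dataset with generated extra missingness plus the amputed ground truth."""

    dataset: Dataset
    amputed_cells: pd.DataFrame  # columns: variant_id, feature, value
    target_level: float
    achieved_observed_missingness: float
    seed: int


def ampute_mcar(ds: Dataset, level: float, seed: int) -> AmputedDataset:
    """Set ``round(level * observed numeric cells)`` uniformly-chosen observed
    numeric cells to missing, recording their original values."""
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    numeric = ds.features.numeric.copy()
    values = numeric.to_numpy()
    observed_flat = np.flatnonzero(~np.isnan(values).ravel())
    n_target = int(round(level * observed_flat.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(observed_flat, size=n_target, replace=False) if n_target else np.array([], dtype=int)
    chosen.sort()
    rows, cols = np.unravel_index(chosen, values.shape)
    cells = pd.DataFrame(
        {
            "variant_id": numeric.index.to_numpy()[rows],
            "feature": numeric.columns.to_numpy()[cols],
            "value": values[rows, cols],
        }
    )
    values[rows, cols] = np.nan
    amputed = pd.DataFrame(values, index=numeric.index, columns=numeric.columns)
    total_cells = values.size
    originally_missing = total_cells - observed_flat.size
    achieved = (originally_missing + n_target) / total_cells if total_cells else 0.0
    new_ds = Dataset(
        FeatureTable(amputed, ds.features.categorical.copy()),
        ds.outcome.copy(),
        ds.consequences.copy(),
    )
    return AmputedDataset(new_ds, cells, level, achieved, seed)


def generate_amputation_suite(
    ds: Dataset,
    levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 100,
    seed: int = 0,
) -> list[AmputedDataset]:
    """|levels| x reps independently-seeded amputed datasets from one master seed."""
    suite = []
    for level in levels:
        for rep in range(reps):
            suite.append(ampute_mcar(ds, level, child_seed(seed, "ampute", level, rep)))
    return suite


def write_amputed(amp: AmputedDataset, prefix: str | Path, schema: TableSchema = TableSchema()) -> None:
    """Write the amputed dataset plus a sidecar of amputed cells and metadata."""
    prefix = Path(prefix)
    write_dataset(amp.dataset, f"{prefix}.csv", schema)
    amp.amputed_cells.to_csv(f"{prefix}_amputed_cells.csv", index=False)
    meta = {
        "target_level": amp.target_level,
        "achieved_observed_missingness": amp.achieved_observed_missingness,
        "seed": amp.seed,
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta))


def read_amputed(prefix: str | Path, schema: TableSchema = TableSchema()) -> AmputedDataset:
    prefix = Path(prefix)
    ds = read_dataset(f"{prefix}.csv", schema)
    cells = pd.read_csv(f"{prefix}_amputed_cells.csv", dtype={"variant_id": str, "feature": str})
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    return AmputedDataset(
        ds, cells, meta["target_level"], meta["achieved_observed_missingness"], meta["seed"]
    )
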