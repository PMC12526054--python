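"""The fit/apply contract shared by all 14 missingness-handling methods.

Methods divide into three families:

* **simple** fills learned per feature from training data (zero, mean,
  median, minimum, maximum, outlier) — fully reusable on new tables;
* **indicator augmentation** — zero fill plus deduplicated binary
  missingness indicators, with the kept indicator set learned on training
  data and therefore reusable;
* **model-based** methods (k-NN, four chained-equations variants, BPCA,
  iterative random forest).  Only k-NN transfers its learned state (the
  complete-case reference set) to new tables; the others re-fit on the table
  being imputed using the stored hyperparameters, mirroring how such methods
  present themselves to a practitioner whose implementation offers no
  out-of-the-box parameter reuse.

``apply`` always returns complete numeric tables (no missing cells) and
never alters observed values; indicator augmentation additionally appends
indicator columns.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .._seeds import child_seed
from ..containers import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationError",
    "InsufficientCompleteCases",
    "SIMPLE_METHODS",
    "CHAINED_METHODS",
    "MULTIPLE_METHODS",
    "METHODS",
    "ImputerSpec",
    "FittedImputer",
    "ImputationResult",
    "fit",
    "apply",
    "method_grid",
    "sample_grid",
    "record_runtime",
]


class ImputationError(RuntimeError):
    """An imputation method could not produce a completed table."""


class InsufficientCompleteCases(ImputationError):
    """k-NN requested more neighbors than there are complete training cases."""


SIMPLE_METHODS = ("zero", "mean", "median", "minimum", "maximum", "outlier")
CHAINED_METHODS = ("pmm", "chained_rf", "chained_linear", "chained_bayes_linear")
#: Methods able to produce m > 1 completed tables per fit (stochastic or
#: multiple-imputation methods).
MULTIPLE_METHODS = frozenset(CHAINED_METHODS) | {"iterative_rf"}
METHODS = SIMPLE_METHODS + ("indicator_augmentation", "knn") + CHAINED_METHODS + (
    "bpca",
    "iterative_rf",
)


@dataclass(frozen=True)
class ImputerSpec:
    """A method plus hyperparameters and a number of imputations m."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    n_imputations: int = 1
    reuse_policy: str = "default"  # "default" | "refit" | "force"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.n_imputations > 1 and self.method not in MULTIPLE_METHODS:
            raise ValueError(f"{self.method} is a single-imputation method (m must be 1)")
        if self.reuse_policy not in ("default", "refit", "force"):
            raise ValueError("reuse_policy must be default, refit or force")


@dataclass(eq=False)
class FittedImputer:
    """A trained missingness-handling method with its learned parameters."""

    spec: ImputerSpec
    feature_names: list[str]
    reuse_supported: bool
    seed: int
    fill_values: pd.Series | None = None
    indicator_columns: list[str] | None = None
    knn_reference: pd.DataFrame | None = None
    knn_scales: pd.Series | None = None


@dataclass(eq=False)
class ImputationResult:
    """m completed numeric tables plus the fitted imputer and timing."""

    tables: list[pd.DataFrame]
    fitted: FittedImputer
    elapsed_seconds: float

    @property
    def elapsed_seconds_per_dataset(self) -> float:
        return self.elapsed_seconds / len(self.tables)


def _as_frame(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    return table.numeric if isinstance(table, FeatureTable) else table


def _check_observed(df: pd.DataFrame) -> None:
    empty = [c for c in df.columns if df[c].notna().sum() == 0]
    if empty:
        raise ImputationError(f"features with zero observed values: {empty}")


def fit(spec: ImputerSpec, train: FeatureTable | pd.DataFrame, seed: int = 0) -> FittedImputer:
    """Learn a method's parameters from training data only."""
    from . import knn as _knn
    from . import simple as _simple

    df = _as_frame(train)
    _check_observed(df)
    names = list(df.columns)
    method = spec.method
    if method in SIMPLE_METHODS:
        fills = _simple.simple_fill_values(method, df)
        return FittedImputer(spec, names, reuse_supported=True, seed=seed, fill_values=fills)
    if method == "indicator_augmentation":
        kept = _simple.indicator_pattern_columns(df)
        return FittedImputer(
            spec,
            names,
            reuse_supported=True,
            seed=seed,
            fill_values=pd.Series(0.0, index=names),
            indicator_columns=kept,
        )
    if method == "knn":
        k = int(spec.hyperparameters.get("k", 1))
        reference, scales = _knn.fit_knn(df, k)
        return FittedImputer(
            spec,
            names,
            reuse_supported=True,
            seed=seed,
            knn_reference=reference,
            knn_scales=scales,
        )
    # Chained-equations, BPCA and iterative RF re-fit at apply time with the
    # stored hyperparameters; fitting validates hyperparameters only.
    if method == "bpca":
        npcs = int(spec.hyperparameters.get("npcs", 2))
        if npcs >= len(names):
            raise ImputationError("bpca requires npcs < number of features")
    return FittedImputer(spec, names, reuse_supported=False, seed=seed)


def apply(
    fitted: FittedImputer, table: FeatureTable | pd.DataFrame, seed: int | None = None
) -> ImputationResult:
    """Impute a table, reusing training parameters where supported.

    For reuse-supported methods (simple, indicator augmentation, k-NN) the
    fills come from training-fitted parameters; the model-based methods
    re-fit on ``table`` using the stored hyperparameters.  Returns m complete
    tables (m > 1 only for stochastic/multiple methods).  Timing covers the
    imputation work only.
    """
    from . import bpca as _bpca
    from . import chained as _chained
    from . import forest as _forest
    from . import knn as _knn
    from . import simple as _simple

    df = _as_frame(table)
    if list(df.columns) != fitted.feature_names:
        raise ImputationError("feature set does not match the fitted imputer")
    if seed is None:
        seed = fitted.seed
    spec = fitted.spec
    method = spec.method
    refit = spec.reuse_policy == "refit"
    if spec.reuse_policy == "force" and not fitted.reuse_supported:
        raise NotImplementedError(f"{method} has no transferable parameter object to reuse")

    start = time.perf_counter()
    if method in SIMPLE_METHODS:
        fills = _simple.simple_fill_values(method, df) if refit else fitted.fill_values
        tables = [df.fillna(fills)]
    elif method == "indicator_augmentation":
        kept = _simple.indicator_pattern_columns(df) if refit else fitted.indicator_columns
        tables = [_simple.apply_indicator_augmentation(df, kept)]
    elif method == "knn":
        k = int(spec.hyperparameters.get("k", 1))
        if refit:
            reference, scales = _knn.fit_knn(df, k)
        else:
            reference, scales = fitted.knn_reference, fitted.knn_scales
        tables = [_knn.apply_knn(df, reference, scales, k)]
    elif method in CHAINED_METHODS:
        tables = _chained.chained_impute(
            df,
            method,
            spec.hyperparameters,
            seed=child_seed(seed, method),
            m=spec.n_imputations,
        )
    elif method == "bpca":
        tables = [
            _bpca.bpca_impute(
                df,
                npcs=int(spec.hyperparameters.get("npcs", 2)),
                maxsteps=int(spec.hyperparameters.get("maxsteps", 100)),
                seed=child_seed(seed, "bpca"),
            )
        ]
    elif method == "iterative_rf":
        tables = _forest.iterative_rf_impute(
            df,
            mtry=spec.hyperparameters.get("mtry", "sqrt"),
            ntree=int(spec.hyperparameters.get("ntree", 100)),
            seed=child_seed(seed, "iterative_rf"),
            m=spec.n_imputations,
        )
    else:  # pragma: no cover - guarded by ImputerSpec validation
        raise ImputationError(f"unknown method {method}")
    elapsed = time.perf_counter() - start

    for t in tables:
        if t[fitted.feature_names].isna().to_numpy().any():
            raise ImputationError(f"{method} left missing cells in its output")
    return ImputationResult(tables, fitted, elapsed)


# ---------------------------------------------------------------------------
# Hyperparameter grids
# ---------------------------------------------------------------------------

def method_grid(method: str, n_features: int | None = None) -> list[dict]:
    """Default hyperparameter grid for a method.

    Values follow common defaults for each method family; grids are
    config-overridable wherever they are consumed.
    """
    if method == "pmm":
        return [
            {"donors": d, "ridge": r, "matchtype": t}
            for d in (1, 3, 5, 10)
            for r in (1e-8, 1e-5, 1e-2)
            for t in (0, 1, 2)
        ]
    if method == "chained_rf":
        return [{"ntree": n} for n in (10, 50, 100, 250)]
    if method in ("chained_linear", "chained_bayes_linear"):
        return [{}]
    if method == "knn":
        return [{"k": k} for k in (1, 2, 5, 10, 20)]
    if method == "bpca":
        hi = min(15, (n_features or 16) - 1)
        return [{"npcs": q, "maxsteps": s} for q in range(2, hi + 1) for s in (100, 500)]
    if method == "iterative_rf":
        return [
            {"mtry": m, "ntree": n}
            for m in ("sqrt", "third", "half")
            for n in (100, 250, 500, 1000)
        ]
    return [{}]  # simple methods and indicator augmentation have no hyperparameters


def sample_grid(
    grid: Sequence[dict], cap: int | None, seed: int = 0
) -> list[dict]:
    """Sample at most ``cap`` configurations uniformly without replacement.

    The sampled configurations keep their original grid order, so downstream
    first-in-grid tie-breaking stays well defined.
    """
    if cap is None or len(grid) <= cap:
        return list(grid)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(grid), size=cap, replace=False))
    return [grid[i] for i in idx]


def record_runtime(result: ImputationResult) -> float:
    """Imputation wall time divided by the number of produced datasets."""
    return result.elapsed_seconds_per_dataset
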