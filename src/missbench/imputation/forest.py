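"""Iterative random-forest imputation (missForest-style).

Missing cells start at per-feature means; features are then visited in order
of increasing missingness, each refitting a random forest of the feature on
all others (over rows where the target is observed) and overwriting its
missing cells with forest predictions.  Iteration stops when the normalised
change in the imputed values *increases* relative to the previous iteration
— the previous iterate is then returned — or when an iteration cap is hit.
m runs differ only by their derived seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .._seeds import child_seed
from .base import ImputationError

__all__ = ["iterative_rf_impute", "resolve_mtry"]

MAX_ITER = 10


def resolve_mtry(mtry: object, n_predictors: int) -> int:
    """Translate an mtry strategy ("sqrt", "third", "half" or an int) into a
    feature count clipped to [1, n_predictors]."""
    if mtry == "sqrt":
        value = int(round(np.sqrt(n_predictors)))
    elif mtry == "third":
        value = n_predictors // 3
    elif mtry == "half":
        value = n_predictors // 2
    else:
        value = int(mtry)  # type: ignore[arg-type]
    return min(max(value, 1), n_predictors)


def iterative_rf_impute(
    df: pd.DataFrame,
    mtry: object = "sqrt",
    ntree: int = 100,
    seed: int = 0,
    m: int = 1,
    max_iter: int = MAX_ITER,
) -> list[pd.DataFrame]:
    if df.shape[1] < 2:
        raise ImputationError("iterative RF imputation needs at least 2 features")
    mask = df.isna().to_numpy()
    original = df.to_numpy()
    if not mask.any():
        return [df.copy() for _ in range(m)]
    col_missing = mask.sum(axis=0)
    visit_order = np.flatnonzero(col_missing > 0)
    visit_order = visit_order[np.argsort(col_missing[visit_order], kind="stable")]
    mtry_int = resolve_mtry(mtry, df.shape[1] - 1)
    means = np.nanmean(original, axis=0)

    results = []
    for run in range(m):
        work = original.copy()
        for col in visit_order:
            work[mask[:, col], col] = means[col]
        prev_gamma = np.inf
        for it in range(max_iter):
            old = work.copy()
            for col in visit_order:
                others = np.ones(df.shape[1], dtype=bool)
                others[col] = False
                obs = ~mask[:, col]
                rf = RandomForestRegressor(
                    n_estimators=ntree,
                    max_features=mtry_int,
                    random_state=child_seed(seed, run, it, int(col)),
                    n_jobs=1,
                )
                rf.fit(work[np.ix_(obs, others)], original[obs, col])
                work[mask[:, col], col] = rf.predict(work[np.ix_(mask[:, col], others)])
            imputed = mask
            num = float(((work - old)[imputed] ** 2).sum())
            den = float((work[imputed] ** 2).sum())
            gamma = num / den if den > 0 else 0.0
            if gamma > prev_gamma:
                work = old  # change grew: keep the previous iterate
                break
            prev_gamma = gamma
            if gamma == 0.0:
                break
        results.append(pd.DataFrame(work, index=df.index, columns=df.columns))
    return results
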