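"""Chained-equations (MICE-style) imputation engine.

Missing cells are initialised by random draws from each feature's observed
values; for a fixed number of sweeps the incomplete features are visited in
order of increasing missingness and each is re-imputed from a univariate
model of that feature on all others, fitted on the rows where the target is
observed.  Four variants share the engine:

``pmm``
    predictive mean matching: a ridge-regularised linear predictor scores
    observed and missing entries (the ``matchtype`` hyperparameter selects
    whether either side uses a Bayesian draw of the coefficients), each
    missing entry draws uniformly among its ``donors`` closest observed
    entries by predicted value and copies the donor's *observed* value;
``chained_linear``
    deterministic prediction from the ridge-regularised linear model;
``chained_bayes_linear``
    coefficients drawn from their posterior, plus Gaussian residual noise;
``chained_rf``
    each missing entry drops down one randomly chosen tree of a random
    forest and draws a donor uniformly from the observed values in the leaf
    it lands in.

m independent chains give multiple imputation.  Donor distance ties are
broken toward the lower observed row index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .base import ImputationError

__all__ = ["chained_impute"]

DEFAULT_SWEEPS = 5
DEFAULT_RIDGE = 1e-5


def _penalized_normal_eq(Z: np.ndarray, y: np.ndarray, ridge: float):
    """Solve the ridge-penalised normal equations; returns (beta, v_inv_factors)."""
    v = Z.T @ Z
    pen = v + np.diag(ridge * np.diag(v))
    try:
        beta = np.linalg.solve(pen, Z.T @ y)
    except np.linalg.LinAlgError as exc:
        raise ImputationError(
            "singular design matrix in chained imputation; set ridge > 0 "
            "(near-duplicate or near-constant features should be filtered upstream)"
        ) from exc
    return beta, pen


def _bayes_draw(Z: np.ndarray, y: np.ndarray, ridge: float, rng: np.random.Generator):
    """Posterior draw of regression coefficients and residual scale."""
    beta_hat, pen = _penalized_normal_eq(Z, y, ridge)
    resid = y - Z @ beta_hat
    df_resid = max(len(y) - Z.shape[1], 1)
    sigma_star = np.sqrt(float(resid @ resid) / rng.chisquare(df_resid))
    v = np.linalg.inv(pen)
    v = (v + v.T) / 2.0
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(v + 1e-10 * np.eye(len(v)))
    beta_star = beta_hat + chol @ rng.standard_normal(Z.shape[1]) * sigma_star
    return beta_hat, beta_star, sigma_star


def _pmm_draw(
    yhat_obs: np.ndarray,
    y_obs: np.ndarray,
    yhat_mis: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised donor matching: copy an observed value whose prediction is
    among the ``donors`` closest to each missing entry's prediction."""
    n_obs = len(yhat_obs)
    d = min(donors, n_obs)
    order = np.lexsort((np.arange(n_obs), yhat_obs))
    sorted_pred = yhat_obs[order]
    n_mis = len(yhat_mis)
    pos = np.searchsorted(sorted_pred, yhat_mis)
    offsets = np.arange(-(d + 1), d + 2)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n_obs - 1)
    diffs = np.abs(sorted_pred[cand] - yhat_mis[:, None])
    dupe = np.zeros_like(diffs, dtype=bool)
    dupe[:, 1:] = cand[:, 1:] == cand[:, :-1]
    diffs[dupe] = np.inf
    tie_key = order[cand]  # original observed row positions
    rows = np.arange(n_mis)[:, None]
    by_tie = np.argsort(tie_key, axis=1, kind="stable")
    diffs_t = diffs[rows, by_tie]
    cand_t = cand[rows, by_tie]
    by_diff = np.argsort(diffs_t, axis=1, kind="stable")  # (diff, then lower row index)
    pick = by_diff[np.arange(n_mis), rng.integers(0, d, size=n_mis)]
    donor_sorted_pos = cand_t[np.arange(n_mis), pick]
    return y_obs[order[donor_sorted_pos]]


def _rf_leaf_draw(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    ntree: int,
    rng: np.random.Generator,
) -> np.ndarray:
    from sklearn.ensemble import RandomForestRegressor

    rf = RandomForestRegressor(
        n_estimators=ntree, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    rf.fit(X_obs, y_obs)
    leaves_obs = rf.apply(X_obs)
    leaves_mis = rf.apply(X_mis)
    n_mis = len(X_mis)
    tree_choice = rng.integers(0, ntree, size=n_mis)
    fill = np.empty(n_mis)
    for t in np.unique(tree_choice):
        targets = np.flatnonzero(tree_choice == t)
        lo = leaves_obs[:, t]
        order = np.argsort(lo, kind="stable")
        sorted_lo = lo[order]
        for r in targets:
            leaf = leaves_mis[r, t]
            left = np.searchsorted(sorted_lo, leaf, side="left")
            right = np.searchsorted(sorted_lo, leaf, side="right")
            fill[r] = y_obs[order[left + rng.integers(0, right - left)]]
    return fill


def _impute_column(
    work: np.ndarray,
    original: np.ndarray,
    col: int,
    obs: np.ndarray,
    mis: np.ndarray,
    method: str,
    hp: dict,
    rng: np.random.Generator,
) -> None:
    others = np.ones(work.shape[1], dtype=bool)
    others[col] = False
    X = work[:, others]
    y_obs = original[obs, col]
    if method == "chained_rf":
        work[mis, col] = _rf_leaf_draw(
            X[obs], y_obs, X[mis], int(hp.get("ntree", 10)), rng
        )
        return
    Z = np.column_stack([np.ones(len(work)), X])
    ridge = float(hp.get("ridge", DEFAULT_RIDGE))
    Zo, Zm = Z[obs], Z[mis]
    if method == "chained_linear":
        beta, _ = _penalized_normal_eq(Zo, y_obs, ridge)
        work[mis, col] = Zm @ beta
    elif method == "chained_bayes_linear":
        _, beta_star, sigma_star = _bayes_draw(Zo, y_obs, ridge, rng)
        work[mis, col] = Zm @ beta_star + rng.standard_normal(len(Zm)) * sigma_star
    elif method == "pmm":
        matchtype = int(hp.get("matchtype", 1))
        donors = int(hp.get("donors", 5))
        if matchtype == 0:
            beta, _ = _penalized_normal_eq(Zo, y_obs, ridge)
            yhat_obs, yhat_mis = Zo @ beta, Zm @ beta
        else:
            beta_hat, beta_star, _ = _bayes_draw(Zo, y_obs, ridge, rng)
            yhat_obs = Zo @ (beta_star if matchtype == 2 else beta_hat)
            yhat_mis = Zm @ beta_star
        work[mis, col] = _pmm_draw(yhat_obs, y_obs, yhat_mis, donors, rng)
    else:  # pragma: no cover
        raise ImputationError(f"unknown chained variant {method}")


def chained_impute(
    df: pd.DataFrame,
    method: str,
    hp: dict,
    seed: int,
    m: int = 1,
    sweeps: int | None = None,
) -> list[pd.DataFrame]:
    """Run m independent chains; returns m completed copies of ``df``."""
    if df.shape[1] < 2:
        raise ImputationError("chained imputation needs at least 2 features")
    sweeps = int(hp.get("sweeps", DEFAULT_SWEEPS)) if sweeps is None else sweeps
    mask = df.isna().to_numpy()
    original = df.to_numpy()
    col_missing = mask.sum(axis=0)
    incomplete = np.flatnonzero(col_missing > 0)
    if incomplete.size == 0:
        return [df.copy() for _ in range(m)]
    visit_order = incomplete[np.argsort(col_missing[incomplete], kind="stable")]

    results = []
    for chain in range(m):
        rng = np.random.default_rng([seed, chain])
        work = original.copy()
        for col in visit_order:
            obs_vals = original[~mask[:, col], col]
            work[mask[:, col], col] = rng.choice(obs_vals, size=int(col_missing[col]), replace=True)
        for _ in range(sweeps):
            for col in visit_order:
                _impute_column(
                    work, original, col, ~mask[:, col], mask[:, col], method, hp, rng
                )
        results.append(pd.DataFrame(work, index=df.index, columns=df.columns))
    return results
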