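"""Bayesian principal-component imputation via expectation-maximisation.

A probabilistic PCA model with an automatic-relevance-determination (ARD)
prior on the loading columns is fitted to the incomplete table by EM:
each E-step computes the posterior of the latent factors for every row from
its observed coordinates only (rows are grouped by missingness pattern so
each pattern is handled with one linear solve), and the M-step re-estimates
the loadings under the ARD penalty together with the residual variance.
The ARD precisions let superfluous components shrink away, so ``npcs`` acts
as an upper bound on the effective dimensionality.  Missing cells are
replaced by the model reconstruction; observed cells are never altered.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .base import ImputationError

logger = logging.getLogger(__name__)

__all__ = ["bpca_impute"]


def bpca_impute(
    df: pd.DataFrame,
    npcs: int,
    maxsteps: int = 100,
    seed: int = 0,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Impute by BPCA reconstruction; deterministic given the inputs.

    If the EM loop has not converged after ``maxsteps`` iterations the
    current reconstruction is returned with a logged warning.
    """
    n, p = df.shape
    if npcs >= p:
        raise ImputationError("bpca requires npcs < number of features")
    X = df.to_numpy()
    mask = np.isnan(X)
    if not mask.any():
        return df.copy()

    mu = np.nanmean(X, axis=0)
    Xc = np.where(mask, 0.0, X - mu)

    # Initialise loadings from the SVD of the mean-filled, centred table.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    q = npcs
    W = (vt[:q].T * (s[:q] / np.sqrt(n)))
    sigma2 = max(float(np.mean(Xc[~mask] ** 2)) - float((W**2).sum()) / p, 1e-6)
    alpha = np.ones(q)

    # Group rows by missingness pattern so each pattern costs one solve.
    pattern_keys = np.packbits(mask, axis=1)
    _, pattern_ids = np.unique(pattern_keys, axis=0, return_inverse=True)

    Zbar = np.zeros((n, q))
    converged = False
    for _ in range(maxsteps):
        W_old = W.copy()
        A = np.zeros((p, q, q))
        b = np.zeros((p, q))
        resid_ss = 0.0
        trace_ss = 0.0
        n_obs_cells = 0
        for pat in np.unique(pattern_ids):
            rows = np.flatnonzero(pattern_ids == pat)
            obs = ~mask[rows[0]]
            if not obs.any():
                Zbar[rows] = 0.0
                continue
            Wo = W[obs]
            C = np.linalg.inv(sigma2 * np.eye(q) + Wo.T @ Wo)
            Zb = Xc[np.ix_(rows, np.flatnonzero(obs))] @ Wo @ C.T
            Zbar[rows] = Zb
            post_cov = sigma2 * C
            patA = Zb.T @ Zb + len(rows) * post_cov
            recon = Zb @ Wo.T
            err = Xc[np.ix_(rows, np.flatnonzero(obs))] - recon
            resid_ss += float((err**2).sum())
            for j in np.flatnonzero(obs):
                A[j] += patA
                b[j] += Zb.T @ Xc[rows, j]
                trace_ss += len(rows) * float(W[j] @ post_cov @ W[j])
            n_obs_cells += len(rows) * int(obs.sum())
        # M-step with ARD shrinkage on loading columns.
        ard = sigma2 * np.diag(alpha)
        for j in range(p):
            W[j] = np.linalg.solve(A[j] + ard, b[j])
        alpha = p / ((W**2).sum(axis=0) + 1e-8)
        sigma2 = max((resid_ss + trace_ss) / max(n_obs_cells, 1), 1e-9)
        if np.linalg.norm(W - W_old) / (np.linalg.norm(W_old) + 1e-12) < tol:
            converged = True
            break
    if not converged:
        logger.warning("bpca EM did not converge within %d steps; returning current reconstruction", maxsteps)

    recon = mu + Zbar @ W.T
    out = np.where(mask, recon, X)
    return pd.DataFrame(out, index=df.index, columns=df.columns)
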