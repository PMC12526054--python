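"""Logistic-regression and random-forest classifiers with MCC-driven
selection of imputation hyperparameters.

LR is a plain maximum-likelihood logistic fit (no tuning).  RF tunes its
``mtry`` (features considered per split) over the candidate values
7/15/23/31/39 — clipped to the available feature count and deduplicated —
by out-of-bag accuracy.  For each imputation hyperparameter configuration
one classifier is trained per completed training table; the configuration
whose classifiers achieve the highest mean training-set MCC wins, ties going
to the earlier grid entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from ._seeds import child_seed
from .imputation import ImputationResult
from .metrics import confusion, mcc

logger = logging.getLogger(__name__)

__all__ = [
    "RF_MTRY_CANDIDATES",
    "RfTuningRecord",
    "TrainedClassifier",
    "SelectionRecord",
    "train",
    "predict",
    "select_imputation_config",
]

RF_MTRY_CANDIDATES = (7, 15, 23, 31, 39)
DEFAULT_RF_NTREE = 500


@dataclass
class RfTuningRecord:
    candidates: list[int]
    oob_scores: list[float]
    selected_mtry: int


@dataclass(eq=False)
class TrainedClassifier:
    kind: str  # "LR" | "RF"
    model: object
    feature_names: list[str]
    training_mcc: float
    tuning: RfTuningRecord | None = None


def _clip_candidates(candidates, n_features: int) -> list[int]:
    clipped = [min(max(c, 1), n_features) for c in candidates]
    seen, out = set(), []
    for c in clipped:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def train(
    kind: str,
    table: pd.DataFrame,
    outcome: pd.Series,
    seed: int = 0,
    rf_ntree: int = DEFAULT_RF_NTREE,
    mtry_candidates: tuple[int, ...] = RF_MTRY_CANDIDATES,
    rf_min_samples_leaf: int = 1,
    lr_max_iter: int = 1000,
) -> TrainedClassifier:
    """Fit one classifier on a completed table; deterministic given the seed."""
    if table.isna().to_numpy().any():
        raise ValueError("classifier input must be a completed table")
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = table.to_numpy(dtype=float)
    tuning = None
    if kind == "LR":
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=lr_max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning("logistic fit hit its iteration cap (possible separation); using current fit")
    elif kind == "RF":
        candidates = _clip_candidates(mtry_candidates, X.shape[1])
        fits, oob = [], []
        for i, mtry in enumerate(candidates):
            rf = RandomForestClassifier(
                n_estimators=rf_ntree,
                max_features=mtry,
                min_samples_leaf=rf_min_samples_leaf,
                oob_score=True,
                random_state=child_seed(seed, "rf", mtry),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                rf.fit(X, y)
            fits.append(rf)
            oob.append(float(rf.oob_score_))
        best = int(np.argmax(oob))  # first maximum wins ties
        model = fits[best]
        tuning = RfTuningRecord(candidates, oob, candidates[best])
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    scores = model.predict_proba(X)[:, 1]
    labels = (scores >= 0.5).astype(int)
    training_mcc = mcc(confusion(labels, y))
    return TrainedClassifier(kind, model, list(table.columns), training_mcc, tuning)


def predict(clf: TrainedClassifier, table: pd.DataFrame):
    """Per-row positive-class score and 0.5-threshold label."""
    if list(table.columns) != clf.feature_names:
        raise ValueError("feature set does not match the trained classifier")
    scores = clf.model.predict_proba(table.to_numpy(dtype=float))[:, 1]
    labels = (scores >= 0.5).astype(int)
    return scores, labels


@dataclass(eq=False)
class SelectionRecord:
    """The winning imputation configuration for one (method, classifier) pair."""

    method: str
    kind: str
    config_scores: list[tuple[dict, float]]  # (hyperparameters, mean training MCC)
    winning_index: int
    classifiers: list[TrainedClassifier] = field(default_factory=list)

    @property
    def winning_config(self) -> dict:
        return self.config_scores[self.winning_index][0]

    @property
    def winning_mcc(self) -> float:
        return self.config_scores[self.winning_index][1]


def select_imputation_config(
    method: str,
    candidates: list[tuple[dict, ImputationResult]],
    kind: str,
    outcome: pd.Series,
    seed: int = 0,
    **train_kwargs,
) -> SelectionRecord:
    """Pick the hyperparameter configuration whose classifiers maximise mean
    training-set MCC; ties break to the earlier grid entry."""
    if not candidates:
        raise ValueError("no imputation configurations to select from")
    config_scores: list[tuple[dict, float]] = []
    classifier_sets: list[list[TrainedClassifier]] = []
    for i, (hp, result) in enumerate(candidates):
        clfs = [
            train(kind, tbl, outcome, seed=child_seed(seed, "select", i, j), **train_kwargs)
            for j, tbl in enumerate(result.tables)
        ]
        mean_mcc = float(np.mean([c.training_mcc for c in clfs]))
        config_scores.append((hp, mean_mcc))
        classifier_sets.append(clfs)
    best = int(np.argmax([s for _, s in config_scores]))  # first max on exact ties
    return SelectionRecord(method, kind, config_scores, best, classifier_sets[best])
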