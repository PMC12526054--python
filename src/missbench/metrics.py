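"""Classification and imputation metrics.

Matthews' correlation coefficient (MCC) is the primary metric because it
stays informative under the heavy class imbalance typical of per-consequence
strata:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

with the convention MCC = 0 whenever a denominator factor is zero.  AUC-ROC
uses the rank-statistic formulation (probability that a random positive
outscores a random negative, ties counted one half).  Imputation accuracy is
RMSE over exactly the amputed cells.  Undefined quantities (single-class
AUC, empty strata, degenerate correlations) are flagged as ``NaN`` rather
than forced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .amputation import AmputedDataset

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "RmseRecord",
    "confusion",
    "mcc",
    "auc_roc",
    "sensitivity",
    "specificity",
    "precision",
    "f1_score",
    "metrics_record",
    "rmse",
    "stratified_metrics",
    "rmse_mcc_association",
    "DEFAULT_STRATA",
]

DEFAULT_STRATA = ("DOWNSTREAM", "UPSTREAM", "INTRONIC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsRecord:
    """One evaluation's worth of classification metrics for a stratum."""

    stratum: str
    n: int
    mcc: float
    auc_roc: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }


@dataclass
class RmseRecord:
    """RMSE over the amputed (generated-missing) cells of one dataset."""

    rmse: float
    n_cells: int


def confusion(labels, truth) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    truth = np.asarray(truth).astype(int)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    tp = int(((labels == 1) & (truth == 1)).sum())
    tn = int(((labels == 0) & (truth == 0)).sum())
    fp = int(((labels == 1) & (truth == 0)).sum())
    fn = int(((labels == 0) & (truth == 1)).sum())
    return ConfusionCounts(tp, tn, fp, fn)


def mcc(c: ConfusionCounts) -> float:
    denom = (
        float(c.tp + c.fn) * float(c.tp + c.fp) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if denom == 0.0:
        return 0.0
    return (float(c.tp) * c.tn - float(c.fp) * c.fn) / np.sqrt(denom)


def auc_roc(scores, truth) -> float:
    """Rank-statistic AUC with midrank tie handling; NaN if one class absent."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = float(ranks[truth == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")


def f1_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else float("nan")


def metrics_record(scores, labels, truth, stratum: str = "ALL") -> MetricsRecord:
    c = confusion(labels, truth)
    return MetricsRecord(
        stratum=stratum,
        n=c.total,
        mcc=mcc(c),
        auc_roc=auc_roc(scores, truth),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        precision=precision(c),
        f1=f1_score(c),
    )


def rmse(amputed: AmputedDataset, completed: pd.DataFrame) -> RmseRecord:
    """RMSE of imputed values against the amputed cells' original values.

    Only generated-missing cells count; originally-missing cells have no
    truth and are excluded.  Cells whose feature was dropped between
    amputation and imputation are skipped (N reflects cells actually
    imputed).  NaN-flagged when no amputed cell survives.
    """
    cells = amputed.amputed_cells
    keep = cells["feature"].isin(completed.columns) & cells["variant_id"].isin(completed.index)
    cells = cells[keep]
    if len(cells) == 0:
        return RmseRecord(float("nan"), 0)
    imputed = completed.to_numpy()[
        completed.index.get_indexer(cells["variant_id"]),
        completed.columns.get_indexer(cells["feature"]),
    ]
    err = imputed - cells["value"].to_numpy()
    return RmseRecord(float(np.sqrt(np.mean(err**2))), len(cells))


def stratified_metrics(
    scores,
    labels,
    truth,
    consequences,
    strata: tuple[str, ...] = DEFAULT_STRATA,
) -> list[MetricsRecord]:
    """Metrics per named consequence stratum plus an "Other" aggregate.

    Empty strata are emitted with NaN metrics (flagged, never zeroed).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    truth = np.asarray(truth).astype(int)
    consequences = np.asarray(consequences, dtype=object)
    records = []
    in_named = np.zeros(len(truth), dtype=bool)
    for name in strata:
        members = consequences == name
        in_named |= members
        if not members.any():
            records.append(
                MetricsRecord(name, 0, *([float("nan")] * 6))
            )
            continue
        records.append(metrics_record(scores[members], labels[members], truth[members], name))
    other = ~in_named
    if other.any():
        records.append(metrics_record(scores[other], labels[other], truth[other], "Other"))
    else:
        records.append(MetricsRecord("Other", 0, *([float("nan")] * 6)))
    return records


def rmse_mcc_association(records: pd.DataFrame) -> pd.Series:
    """Per-method Pearson correlation between imputation RMSE and test MCC.

    ``records`` is long-format with columns (method, rmse, mcc), one row per
    amputed dataset.  Methods with < 3 datasets or degenerate variance are
    flagged NaN.
    """
    out = {}
    for method, grp in records.groupby("method", sort=False):
        x = grp["rmse"].to_numpy(dtype=float)
        y = grp["mcc"].to_numpy(dtype=float)
        if len(grp) < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
            out[method] = float("nan")
            continue
        out[method] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="rmse_mcc_pearson")
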