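"""Prediction performance: sensitivity, specificity, MCC, per-protein ROC.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP))

summarize hard predictions; a metric whose denominator vanishes is reported
as undefined (NaN), never silently as 0. ROC curves are computed one protein
at a time on that protein's own residues and then averaged vertically: the
true-positive rate is linearly interpolated onto a common false-positive-rate
grid (0 to 1, step 0.01) and averaged across proteins. Proteins lacking
either class are excluded from the average and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts", "MetricsReport", "ROCCurve",
    "confusion", "metrics", "mcc_score", "per_protein_roc", "rank_report",
]

FPR_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    mcc: float
    counts: ConfusionCounts
    feature_set: str = ""
    mode: str = ""  # "balanced" | "unbalanced"

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "feature_set": self.feature_set, "mode": self.mode,
        }


def confusion(predicted: np.ndarray, actual: np.ndarray) -> ConfusionCounts:
    """Standard 2x2 counts with the catalytic class as positive."""
    predicted = np.asarray(predicted).astype(bool)
    actual = np.asarray(actual).astype(bool)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(predicted & actual)),
        fp=int(np.sum(predicted & ~actual)),
        tn=int(np.sum(~predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
    )


def mcc_score(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; NaN when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fn) * (c.tn + c.fp)
    )
    if denom == 0:
        return float("nan")
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def metrics(counts: ConfusionCounts, feature_set: str = "", mode: str = "") -> MetricsReport:
    """Sensitivity, specificity and MCC from confusion counts."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        mcc=mcc_score(counts),
        counts=counts,
        feature_set=feature_set,
        mode=mode,
    )


@dataclass
class ROCCurve:
    """Vertically averaged per-protein ROC."""

    fpr: np.ndarray
    mean_tpr: np.ndarray
    per_protein: dict[tuple[str, str], np.ndarray]
    n_excluded: int

    @property
    def n_proteins(self) -> int:
        return len(self.per_protein)

    def auc(self) -> float:
        return float(np.trapezoid(self.mean_tpr, self.fpr))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fpr": self.fpr,
            "mean_tpr": self.mean_tpr,
            "n_proteins": self.n_proteins,
        })


def per_protein_roc(predictions: pd.DataFrame) -> ROCCurve:
    """Average per-protein ROC curves on a common FPR grid.

    ``predictions`` needs columns pdb_id, chain_id, probability, y_true.
    Each eligible protein (>=1 catalytic and >=1 noncatalytic residue)
    contributes one ROC curve from a threshold sweep over its probabilities;
    TPR is interpolated linearly onto the grid and averaged pointwise.
    """
    curves: dict[tuple[str, str], np.ndarray] = {}
    n_excluded = 0
    for (pdb_id, chain_id), grp in predictions.groupby(["pdb_id", "chain_id"]):
        y = grp["y_true"].to_numpy()
        if y.sum() == 0 or y.sum() == len(y):
            n_excluded += 1
            continue
        fpr, tpr, _ = roc_curve(y, grp["probability"].to_numpy())
        curves[(pdb_id, chain_id)] = np.interp(FPR_GRID, fpr, tpr)
    if not curves:
        raise ValueError("no protein has both classes; ROC undefined")
    mean_tpr = np.mean(np.vstack(list(curves.values())), axis=0)
    return ROCCurve(
        fpr=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        per_protein=curves,
        n_excluded=n_excluded,
    )


def rank_report(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-catalytic-residue ranks: one row per labelled residue.

    Returns columns protein (``pdb:chain``), residue (``<aa?><res_seq><icode>``),
    rank — the residue's position when its protein's residues are sorted by
    descending predicted probability.
    """
    cat = predictions[predictions["y_true"] == 1]
    rows = [
        {
            "protein": f"{r.pdb_id.upper()}:{r.chain_id}",
            "residue": f"{r.res_seq}{r.icode}",
            "rank": int(r.rank),
            "probability": float(r.probability),
        }
        for r in cat.itertuples()
    ]
    return pd.DataFrame(rows, columns=["protein", "residue", "rank", "probability"])
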