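"""Performance summaries: confusion-matrix metrics, class-probability
five-number summaries and selection-overlap (Venn) counts.

A note on naming: the column-wise per-class metric is reported here as
``specificity_as_printed`` because that is the label multi-class
confusion tables in this application area often carry; numerically it is
the positive predictive value (diagonal count divided by the predicted
class total), not the true-negative rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion_metrics",
    "probability_summary",
    "selection_overlap",
]


@dataclass
class ConfusionMatrix:
    """k x k count table; rows = true class, columns = predicted class."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if not counts.index.equals(counts.columns):
            raise ValueError("row and column labels must match")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.to_numpy().sum() == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def classes(self) -> pd.Index:
        return self.counts.index

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path: str) -> None:
        """Table layout with sensitivity as final column, PPV as final row."""
        m = confusion_metrics(self)
        out = self.counts.astype(float).copy()
        out["Sensitivity [%]"] = m["sensitivity"].round(1)
        bottom = m["specificity_as_printed"].round(1)
        bottom.name = "Specificity [%]"
        out = pd.concat([out, bottom.to_frame().T])
        out.to_csv(path)


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Row-wise sensitivity, column-wise PPV, overall accuracy and error.

    All values are percentages.  ``sensitivity(c) = 100 * cm[c, c] /
    row_sum(c)``; ``specificity_as_printed(c) = 100 * cm[c, c] /
    col_sum(c)`` (the positive predictive value).  Classes with a zero
    row/column sum get NaN for the affected metric.  ``*_rounded`` entries
    are rounded to one decimal for report output.
    """
    counts = cm.counts.to_numpy(dtype=float)
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, 100.0 * diag / row, np.nan)
        ppv = np.where(col > 0, 100.0 * diag / col, np.nan)
    accuracy = 100.0 * diag.sum() / counts.sum()
    sens = pd.Series(sens, index=cm.classes, name="sensitivity")
    ppv = pd.Series(ppv, index=cm.classes, name="specificity_as_printed")
    return {
        "sensitivity": sens,
        "specificity_as_printed": ppv,
        "accuracy": float(accuracy),
        "error": float(100.0 - accuracy),
        "sensitivity_rounded": sens.round(1),
        "specificity_as_printed_rounded": ppv.round(1),
        "accuracy_rounded": round(accuracy, 1),
        "error_rounded": round(100.0 - accuracy, 1),
    }


def probability_summary(proba, true_labels, classes=None) -> pd.DataFrame:
    """Five-number summaries of class probabilities, grouped by true class.

    ``proba`` is (n, k) with rows summing to 1 (NaN rows -- samples with
    undefined OOB probability -- are dropped).  Returns a DataFrame indexed
    by (true_class, predicted_class) with columns min/q1/median/q3/max;
    quartiles use linear interpolation.  Empty classes yield NaN rows.
    """
    proba = np.asarray(proba, dtype=float)
    labels = pd.Series(np.asarray(true_labels))
    if classes is None:
        classes = np.unique(labels)
    classes = list(classes)
    if proba.shape[1] != len(classes):
        raise ValueError("probability columns do not match the class list")
    ok = ~np.isnan(proba).any(axis=1)
    sums = proba[ok].sum(axis=1)
    if ok.any() and not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("probability rows must sum to 1")
    rows = []
    for true_c in classes:
        members = ok & (labels == true_c).to_numpy()
        for j, pred_c in enumerate(classes):
            vals = proba[members, j]
            if vals.size == 0:
                stats = [np.nan] * 5
            else:
                stats = [
                    float(np.min(vals)),
                    float(np.quantile(vals, 0.25)),
                    float(np.median(vals)),
                    float(np.quantile(vals, 0.75)),
                    float(np.max(vals)),
                ]
            rows.append((true_c, pred_c, *stats))
    return pd.DataFrame(
        rows, columns=["true_class", "predicted_class", "min", "q1", "median", "q3", "max"]
    ).set_index(["true_class", "predicted_class"])


def selection_overlap(selected_sets: Sequence, names: Sequence[str] | None = None) -> dict:
    """Counts of every intersection region of 2..4 selected-feature sets.

    Region keys are tuples of member names, e.g. ``('smd',)`` for features
    exclusive to the first set, ``('smd', 'boruta')`` for the overlap.
    Region counts sum to the size of the union.
    """
    sets = [set(s) for s in selected_sets]
    if len(sets) < 2:
        raise ValueError("need at least two selection results")
    if len(sets) > 4:
        raise ValueError("at most four sets supported")
    if names is None:
        names = [f"set{i + 1}" for i in range(len(sets))]
    names = list(names)
    regions: dict[tuple, int] = {}
    for r in range(1, len(sets) + 1):
        for members in combinations(range(len(sets)), r):
            inside = set.intersection(*(sets[i] for i in members))
            for i in range(len(sets)):
                if i not in members:
                    inside -= sets[i]
            regions[tuple(names[i] for i in members)] = len(inside)
    return regions
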