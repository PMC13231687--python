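"""Performance metrics, MCC-quartile grouping, and paired significance tests.

Balanced accuracy and the Matthews correlation coefficient are computed
directly from confusion counts:

    BA  = 1/2 (TP/(TP+FN) + TN/(TN+FP))
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.  ROC-AUC uses
the midrank (ties count half) convention.  Per-assay results are grouped by
MCC quartiles — "positive" above Q3, "negative" below Q1, "interquartile"
in between — and representation pairs are compared by two-sided Wilcoxon
signed-rank tests with Holm step-down adjustment across one family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "ConfusionCounts",
    "AssayResult",
    "balanced_accuracy",
    "mcc",
    "roc_auc",
    "group_by_mcc",
    "paired_wilcoxon_holm",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InputError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]):
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise InputError("label/prediction length mismatch")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        )


@dataclass(frozen=True)
class AssayResult:
    """Metrics of one (test assay, scheme, representation, algorithm) cell."""

    test_assay: str
    scheme: str
    representation: str
    algo: str
    ba: float
    roc_auc: float
    mcc: float
    group: str = ""  # "positive" | "interquartile" | "negative" once grouped


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity; needs both classes present."""
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        raise InputError("balanced accuracy undefined without both classes")
    return 0.5 * (c.tp / pos + c.tn / neg)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 on a vanishing denominator."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative (midrank)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise InputError("ROC-AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def group_by_mcc(results: Sequence[AssayResult]) -> list[AssayResult]:
    """Label each result positive / interquartile / negative by MCC quartiles.

    Quartiles are computed per (scheme, representation, algo) cell with
    linear interpolation; "positive" means MCC strictly above Q3,
    "negative" strictly below Q1.
    """
    by_cell: dict[tuple, list[AssayResult]] = {}
    for r in results:
        by_cell.setdefault((r.scheme, r.representation, r.algo), []).append(r)
    out = []
    for cell in by_cell.values():
        values = np.array([r.mcc for r in cell], dtype=float)
        q1, q3 = np.percentile(values, [25, 75])
        for r in cell:
            if r.mcc > q3:
                group = "positive"
            elif r.mcc < q1:
                group = "negative"
            else:
                group = "interquartile"
            out.append(replace(r, group=group))
    return out


def paired_wilcoxon_holm(
    results_by_representation: Mapping[str, pd.Series],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests with Holm adjustment.

    Each value of the mapping is a per-assay metric vector indexed by test
    assay; all vectors must be aligned on the same assays.  Pairs with all
    differences zero cannot be tested and are flagged ``zero_differences``
    (reported non-significant, p = 1).  The exact null distribution is used
    for n <= 25 untied non-zero differences, the normal approximation
    otherwise.
    """
    kinds = sorted(results_by_representation)
    if len(kinds) < 2:
        raise InputError("need at least two representations to compare")
    index = results_by_representation[kinds[0]].index
    for k in kinds[1:]:
        if not results_by_representation[k].index.equals(index):
            raise InputError(f"assay sets misaligned for representation {k!r}")

    rows = []
    for a, b in itertools.combinations(kinds, 2):
        x = results_by_representation[a].to_numpy(dtype=float)
        y = results_by_representation[b].to_numpy(dtype=float)
        diffs = x - y
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            rows.append({"pair": f"{a} vs {b}", "raw_p": 1.0,
                         "flag": "zero_differences"})
            continue
        has_ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method,
                             zero_method="wilcox")
        rows.append({"pair": f"{a} vs {b}", "raw_p": float(res.pvalue), "flag": ""})

    frame = pd.DataFrame(rows)
    reject, adjusted, _, _ = multipletests(frame["raw_p"], alpha=alpha,
                                           method="holm")
    frame["adjusted_p"] = adjusted
    frame["significant"] = reject & (frame["flag"] == "")
    return frame[["pair", "raw_p", "adjusted_p", "significant", "flag"]]
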