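"""Held-out performance metrics: ROC/AUC, confusion battery, chi-square.

AUC uses the midrank (Mann-Whitney) convention: the probability that a
random case outscores a random control, ties counted one half.  Predictive
values that are undefined because no positive (or negative) call was made
are reported as ``None`` — "N/A" — rather than zero.  The 2x2 chi-square
is Pearson's without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, rankdata

__all__ = ["MetricsReport", "roc_auc", "roc_curve", "confusion_metrics",
           "pearson_chi2", "prevalence"]


@dataclass
class MetricsReport:
    """Test-set performance at one operating threshold.

    Rates are proportions in [0, 1]; ``ppv``/``npv`` are ``None`` when no
    positive/negative calls were made.  ``as_row`` renders the battery
    the way the comparison tables print it (AUC to 2 dp, rates as
    percentages to 1 dp, N/A for undefined entries).
    """

    auc: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    classification_rate: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)

    def as_row(self) -> dict:
        def pct(v):
            return "N/A" if v is None else f"{100 * v:.1f}%"

        return {
            "AUC": f"{self.auc:.2f}",
            "Sensitivity": pct(self.sensitivity),
            "Specificity": pct(self.specificity),
            "PPV": pct(self.ppv),
            "NPV": pct(self.npv),
            "Classification rate": pct(self.classification_rate),
        }


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def roc_auc(scores, labels) -> float:
    """Midrank AUC: P(score_case > score_control) + P(tie)/2."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # midranks
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, labels) -> np.ndarray:
    """(FPR, TPR) points, one per distinct score plus (0,0) and (1,1).

    Thresholds sweep the distinct scores in decreasing order with the
    "predict positive iff score >= t" convention; the trapezoidal area
    under the returned polyline equals :func:`roc_auc`.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n1 = y.sum()
    n0 = y.size - n1
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    last = np.nonzero(np.diff(s, append=-np.inf))[0]  # block ends
    pts = [(0.0, 0.0)]
    for i in last:
        pts.append((fps[i] / n0, tps[i] / n1))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.array(pts)


def confusion_metrics(scores, labels, threshold: float) -> MetricsReport:
    """Confusion battery at ``score >= threshold`` plus midrank AUC."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return MetricsReport(
        auc=roc_auc(scores, labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp > 0 else None,
        npv=tn / (tn + fn) if tn + fn > 0 else None,
        classification_rate=(tp + tn) / labels.size,
        threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn)


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ValueError("all margins must be positive")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def prevalence(table: pd.DataFrame) -> float:
    """Unweighted case proportion of a cohort table."""
    if len(table) == 0:
        raise ValueError("empty table")
    return float((table["outcome"] == 1).mean())
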