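"""Classification statistics: confusion counts, point metrics, curves,
repeat summaries and run comparisons.

Point metrics follow the usual definitions — accuracy, sensitivity,
specificity and precision as percentages and the Matthews correlation
coefficient in [-1, 1].  Ratios with zero denominators are reported as
absent (``None``), never coerced to 0.  ROC and precision-recall curves
are threshold sweeps over the scores (via scikit-learn) with areas by
the trapezoidal rule.  Repeated runs are summarized by mean and relative
standard deviation, and two repeated-run populations are compared with
the two-sided Wilcoxon rank-sum and two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    AC: float | None   # percent
    SE: float | None   # percent
    SP: float | None   # percent
    PR: float | None   # percent
    MCC: float | None
    ROCA: float | None = None
    PRCA: float | None = None

    def as_dict(self) -> dict:
        return {
            "AC": self.AC, "SE": self.SE, "SP": self.SP, "PR": self.PR,
            "MCC": self.MCC, "ROCA": self.ROCA, "PRCA": self.PRCA,
        }


def confusion(labels, probabilities, cutoff: float = 0.5) -> ConfusionCounts:
    """Tally counts with the strict decision rule: positive iff p > cutoff."""
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p > cutoff
    return ConfusionCounts(
        TP=int(((y == 1) & pred).sum()),
        FP=int(((y == 0) & pred).sum()),
        TN=int(((y == 0) & ~pred).sum()),
        FN=int(((y == 1) & ~pred).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """AC/SE/SP/PR as percentages and MCC; absent where undefined."""
    if c.total == 0:
        raise ValueError("cannot compute metrics over zero records")
    mcc_den = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (
        (c.TP * c.TN - c.FP * c.FN) / math.sqrt(mcc_den) if mcc_den else None
    )
    return MetricsReport(
        AC=_ratio(c.TP + c.TN, c.total),
        SE=_ratio(c.TP, c.TP + c.FN),
        SP=_ratio(c.TN, c.TN + c.FP),
        PR=_ratio(c.TP, c.TP + c.FP),
        MCC=mcc,
    )


def _check_both_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("curve computation requires both classes present")


def roc_points(labels, probabilities) -> np.ndarray:
    """(FPR, TPR) points of the ROC curve, monotone in FPR."""
    y = np.asarray(labels, dtype=np.int64)
    _check_both_classes(y)
    fpr, tpr, _ = roc_curve(
        y, np.asarray(probabilities, dtype=np.float64), drop_intermediate=False
    )
    return np.column_stack([fpr, tpr])


def pr_points(labels, probabilities) -> np.ndarray:
    """(recall, precision) points of the precision-recall curve."""
    y = np.asarray(labels, dtype=np.int64)
    _check_both_classes(y)
    precision, recall, _ = precision_recall_curve(
        y, np.asarray(probabilities, dtype=np.float64)
    )
    # scikit-learn appends the (recall 0, precision 1) anchor; keep the
    # sweep itself, ordered by increasing recall, without interpolation
    # beyond the trapezoid used for the area.
    pts = np.column_stack([recall, precision])[::-1]
    return pts


def curve_area(curve: np.ndarray) -> float:
    """Trapezoidal area under a curve given as (x, y) rows."""
    pts = np.asarray(curve, dtype=np.float64)
    order = np.argsort(pts[:, 0], kind="stable")
    return float(np.trapezoid(pts[order, 1], pts[order, 0]))


def roc_auc(labels, probabilities) -> float:
    return curve_area(roc_points(labels, probabilities))


def pr_auc(labels, probabilities) -> float:
    return curve_area(pr_points(labels, probabilities))


def full_report(labels, probabilities, cutoff: float = 0.5) -> MetricsReport:
    """Point metrics at the cutoff plus trapezoidal ROC and PR areas."""
    point = metrics(confusion(labels, probabilities, cutoff))
    return MetricsReport(
        AC=point.AC, SE=point.SE, SP=point.SP, PR=point.PR, MCC=point.MCC,
        ROCA=roc_auc(labels, probabilities),
        PRCA=pr_auc(labels, probabilities),
    )


@dataclass(frozen=True)
class RepeatSummary:
    mean: float
    rsd: float  # percent: 100 * sample std / mean


def repeat_summary(values) -> RepeatSummary:
    """Mean and relative standard deviation (percent, sample std) of repeats."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("repeat summary needs at least 2 values")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("relative standard deviation is defined only for positive means")
    return RepeatSummary(mean=mean, rsd=float(100.0 * v.std(ddof=1) / mean))


def compare_runs(a, b) -> dict[str, float | None]:
    """Two-sided Wilcoxon rank-sum and two-sample KS p-values.

    Degenerate input (every value in both samples identical) yields
    absent p-values with a warning.
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values tied; comparison tests are undefined", stacklevel=2)
        return {"p_ranksum": None, "p_ks": None}
    ranksum = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    ks = stats.ks_2samp(x, y, alternative="two-sided")
    return {"p_ranksum": float(ranksum.pvalue), "p_ks": float(ks.pvalue)}
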