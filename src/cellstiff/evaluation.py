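"""Classification metrics, modulus-threshold labeling, distribution
fits, and group-comparison statistics.

Metric definitions follow the usual binary-classification conventions
(stiff = positive class, hard labels at p >= 0.5, AUC by trapezoidal
integration of the ROC). Intermediate-stiffness cells are labeled from
reference AFM moduli by interval rules — e.g. 200 +- 100 Pa as soft and
>= 3 kPa as stiff for MSCs — with everything in between excluded.

Group comparisons mirror common practice in cell-mechanics studies: a
normality gate (Shapiro-Wilk at alpha 0.05 on every group) selects
between parametric (t-test / one-way ANOVA with Tukey's HSD) and
non-parametric (Mann-Whitney U / Kruskal-Wallis) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as sk_auc, confusion_matrix, roc_curve


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: np.ndarray  # (k, 2) columns fpr, tpr
    confusion: np.ndarray  # 2x2, rows true, cols predicted

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "confusion": self.confusion.tolist()}


@dataclass
class ModulusLabelRule:
    """Interval rule mapping a measured modulus to soft/stiff/excluded."""

    soft_interval: tuple[float, float]
    stiff_threshold: float

    def __post_init__(self):
        lo, hi = self.soft_interval
        if not 0 < lo <= hi:
            raise ValueError("soft interval must be positive and ordered")
        if hi > self.stiff_threshold:
            raise ValueError("soft interval must not cross stiff threshold")


# The MSC study rule: 200 +- 100 Pa soft, >= 3 kPa stiff.
MSC_RULE = ModulusLabelRule(soft_interval=(100.0, 300.0),
                            stiff_threshold=3000.0)
# RAW264.7: 200 +- 100 Pa soft; "2 +- 1 kPa or above" stiff, read as the
# lower band edge (>= 1 kPa). Adjust stiff_threshold to 2000 for the
# stricter reading.
RAW_RULE = ModulusLabelRule(soft_interval=(100.0, 300.0),
                            stiff_threshold=1000.0)


def classification_metrics(true_labels, stiff_probs,
                           threshold: float = 0.5) -> MetricsReport:
    """Accuracy/precision/recall/F1/AUC/ROC/confusion for binary labels.

    ``true_labels`` are 0/1 (1 = stiff) or "soft"/"stiff" strings;
    ``stiff_probs`` are stiff-class probabilities. Hard labels are
    p >= threshold. Single-class truth raises (AUC undefined).
    """
    y = np.asarray([1 if t in (1, "stiff", True) else 0
                    for t in np.asarray(true_labels).tolist()])
    p = np.asarray(stiff_probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must align")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single true class")

    pred = (p >= threshold).astype(int)
    cm = confusion_matrix(y, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) \
        if precision + recall else 0.0
    fpr, tpr, _ = roc_curve(y, p)
    return MetricsReport(
        accuracy=float((tp + tn) / cm.sum()),
        precision=float(precision), recall=float(recall), f1=float(f1),
        auc=float(sk_auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
        confusion=cm)


def label_by_modulus(modulus_pa: float, rule: ModulusLabelRule) -> str:
    """soft if E in the (closed) soft interval, stiff if E >= threshold,
    else excluded."""
    if modulus_pa <= 0:
        raise ValueError("modulus must be positive")
    lo, hi = rule.soft_interval
    if lo <= modulus_pa <= hi:
        return "soft"
    if modulus_pa >= rule.stiff_threshold:
        return "stiff"
    return "excluded"


def fit_gaussian(values) -> tuple[float, float]:
    """Maximum-likelihood normal fit (mean, sd) of a modulus sample."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.allclose(v, v[0]):
        raise ValueError("zero-variance sample: degenerate Gaussian fit")
    mu, sigma = stats.norm.fit(v)
    return float(mu), float(sigma)


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    normal: bool
    posthoc: list = field(default_factory=list)  # (i, j, p) for >2 groups


def compare_groups(groups, alpha: float = 0.05) -> GroupComparison:
    """Choose and run the appropriate location test across groups.

    All groups normal by Shapiro-Wilk (at ``alpha``): two groups get a
    two-sample t-test, more get one-way ANOVA with Tukey's HSD post hoc.
    Otherwise: Mann-Whitney U or Kruskal-Wallis.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs at least 3 observations")

    normal = all(
        len(np.unique(g)) > 1 and stats.shapiro(g).pvalue > alpha
        for g in groups)
    posthoc = []
    if len(groups) == 2:
        if normal:
            res = stats.ttest_ind(groups[0], groups[1])
            name = "t-test"
        else:
            res = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided")
            name = "mann-whitney-u"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if normal:
            res = stats.f_oneway(*groups)
            name = "anova-tukey"
            tk = stats.tukey_hsd(*groups)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    posthoc.append((i, j, float(tk.pvalue[i, j])))
        else:
            res = stats.kruskal(*groups)
            name = "kruskal-wallis"
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(test_name=name, statistic=stat, p_value=p,
                           normal=normal, posthoc=posthoc)
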