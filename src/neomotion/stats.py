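"""Classifier evaluation and group-comparison statistics.

Covers the evaluation toolkit of the risk-classification analysis:

* ROC/AUC of predicted high-risk probabilities (trapezoidal area, which
  equals the Mann–Whitney concordance probability with ties counted ½);
* the operating threshold that maximizes the F-measure, with
  sensitivity, specificity and the confusion matrix at that threshold;
* DeLong's test for comparing two AUCs via placement-value variances,
  in both paired and unpaired form;
* the Brunner–Munzel rank test of the relative effect
  ``P(X < Y) + ½ P(X = Y)`` for group comparisons of continuous
  covariates;
* Fisher's exact test for 2x2 contingency tables (e.g. sex by risk
  group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "roc_auc",
    "best_f_threshold",
    "delong_test",
    "brunner_munzel",
    "fisher_exact",
]


@dataclass
class RocResult:
    """ROC curve with AUC and the F-optimal operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    f_measure: float
    confusion: np.ndarray  # [[TP, FN], [FP, TN]]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> RocResult:
    """ROC over all distinct score thresholds, AUC by the trapezoid rule.

    Positive class is high risk (label 1).  The returned result also
    carries the F-measure-optimal operating point from
    :func:`best_f_threshold`.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    thr, sens, spec, f, conf = best_f_threshold(scores, labels)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, threshold=thr,
                     sensitivity=sens, specificity=spec, f_measure=f,
                     confusion=conf)


def best_f_threshold(scores, labels):
    """Operating threshold maximizing the F-measure.

    Candidate thresholds are midpoints between consecutive distinct
    scores (plus sentinels below the minimum and above the maximum); a
    sample is called positive when its score is >= the threshold.
    ``F = 2·precision·recall / (precision + recall)``, with F = 0 when no
    positive call is made.  Ties in F break toward the lower threshold —
    the more sensitive operating point.

    Returns ``(threshold, sensitivity, specificity, f_measure,
    confusion)`` with confusion ``[[TP, FN], [FP, TN]]``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    distinct = np.unique(scores)
    cands = np.concatenate([
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 1.0],
    ])
    best = None
    for thr in cands:  # ascending: first max wins -> lowest threshold
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        if best is None or f > best[3] + 1e-12:
            sens = recall
            spec = tn / (tn + fp) if tn + fp else 0.0
            best = (float(thr), sens, spec, f,
                    np.array([[tp, fn], [fp, tn]]))
    return best


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values and the AUC they average to."""
    v_pos = np.array([
        np.mean((p > neg) + 0.5 * (p == neg)) for p in pos
    ])
    v_neg = np.array([
        np.mean((pos > n) + 0.5 * (pos == n)) for n in neg
    ])
    return v_pos, v_neg, float(v_pos.mean())


def _auc_variance(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    v_pos, v_neg, auc = _placements(pos, neg)
    var = (np.var(v_pos, ddof=1) / len(pos)
           + np.var(v_neg, ddof=1) / len(neg))
    return auc, var, (v_pos, v_neg)


def delong_test(scores_a, labels_a, scores_b, labels_b, paired: bool = False):
    """DeLong comparison of two AUCs.

    Variances come from the empirical variance of placement values.  In
    the paired form (same subjects scored by two models) the covariance
    of placements is subtracted; in the unpaired form (disjoint subject
    sets, e.g. sleep vs awake datasets of different sizes) the variances
    simply add.

    Returns ``(auc_a, auc_b, z, p)``; ``p`` is two-sided normal.  A
    degenerate (zero) variance yields ``z = nan, p = nan``.
    """
    auc_a, var_a, pl_a = _auc_variance(scores_a, labels_a)
    auc_b, var_b, pl_b = _auc_variance(scores_b, labels_b)
    _check_two_classes(np.asarray(labels_a, dtype=int))
    _check_two_classes(np.asarray(labels_b, dtype=int))
    if paired:
        if len(pl_a[0]) != len(pl_b[0]) or len(pl_a[1]) != len(pl_b[1]):
            raise ValueError("paired comparison requires identical subject sets")
        cov = (_cov(pl_a[0], pl_b[0]) / len(pl_a[0])
               + _cov(pl_a[1], pl_b[1]) / len(pl_a[1]))
        var = var_a + var_b - 2 * cov
    else:
        var = var_a + var_b
    if var <= 0:
        if np.isclose(auc_a, auc_b):
            return auc_a, auc_b, np.nan, np.nan
        return auc_a, auc_b, np.nan, np.nan
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return 0.0
    return float(np.cov(a, b, ddof=1)[0, 1])


def brunner_munzel(x, y):
    """Brunner–Munzel test of the relative effect ``p̂ = P(X<Y) + ½P(X=Y)``.

    Uses midranks over the pooled sample, the studentized statistic with
    Satterthwaite-approximated degrees of freedom, and a two-sided t
    p-value.  Fully separated samples (zero rank variance in both
    groups) leave the statistic undefined: ``(inf·sign, nan, nan, p̂)``
    is returned with p̂ at its boundary value.

    Returns ``(statistic, df, p_value, relative_effect)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx, ry = ranks[:n1], ranks[n1:]
    rx_within = sps.rankdata(x)
    ry_within = sps.rankdata(y)
    p_hat = (ry.mean() - (n2 + 1) / 2) / n1  # P(X<Y) + 0.5 P(X=Y)

    sx2 = np.var(rx - rx_within, ddof=1)
    sy2 = np.var(ry - ry_within, ddof=1)
    if sx2 == 0 and sy2 == 0:
        stat = np.inf if p_hat > 0.5 else (-np.inf if p_hat < 0.5 else 0.0)
        return stat, np.nan, np.nan, float(p_hat)
    stat = n1 * n2 * (ry.mean() - rx.mean()) / (
        (n1 + n2) * np.sqrt(n1 * sx2 + n2 * sy2))
    num = (n1 * sx2 + n2 * sy2) ** 2
    den = (n1 * sx2) ** 2 / (n1 - 1) + (n2 * sy2) ** 2 / (n2 - 1)
    df = num / den
    p = 2.0 * sps.t.sf(abs(stat), df)
    return float(stat), float(df), float(p), float(p_hat)


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table.

    Two-sided p is the total probability, under the fixed-margin
    hypergeometric null, of tables no more probable than the observed
    one.  A zero margin makes every table certain: p = 1.

    Returns ``(odds_ratio, p_two_sided)``.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        a, b, c, d = table.ravel()
        orat = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan)
        return float(orat), 1.0
    orat, p = sps.fisher_exact(table, alternative="two-sided")
    return float(orat), float(p)
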