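"""Classification metrics and statistical comparison machinery.

Threshold metrics follow the usual confusion-count formulas with explicit
zero-division conventions.  AUC uses the Mann–Whitney rank statistic with
half credit for ties; AUPR is the step-wise precision–recall integral
(no linear interpolation).  Model comparison uses the paired DeLong test
for AUC and stratified bootstrap resampling for threshold metrics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "confusion_counts",
    "confusion_metrics",
    "roc_auc",
    "aupr",
    "delong_test",
    "stratified_bootstrap",
    "BootstrapResult",
]


def confusion_counts(scores, labels, threshold: float):
    """(TP, FP, FN, TN) for the rule score ≥ threshold → positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return tp, fp, fn, tn


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Precision, recall, F1, MCC and balanced accuracy from counts.

    Zero-division conventions: precision 0 if TP+FP = 0; recall 0 if
    TP+FN = 0; F1 = 0 if precision+recall = 0; MCC = 0 if any denominator
    factor is 0; each BACC term 0 if its denominator is 0.
    """
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    bacc = 0.5 * (sens + spec)
    return {"pre": pre, "rec": rec, "f1": f1, "mcc": float(mcc), "bacc": bacc}


def roc_auc(scores, labels) -> float:
    """ROC AUC via the Mann–Whitney U statistic, half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision–recall curve by step-wise integration.

    AP = Σ (R_k − R_{k−1}) · P_k over descending unique score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    tp_cum = np.cumsum(y_sorted)
    pred_cum = np.arange(1, labels.size + 1)
    # thresholds at the last element of each tied block
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp_cum[is_last].astype(float)
    pp = pred_cum[is_last].astype(float)
    precision = tp / pp
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """Mid-rank placement values used by the DeLong covariance estimator."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(all_scores)
    pos_ranks = rankdata(pos_scores)
    neg_ranks = rankdata(neg_scores)
    v_pos = (ranks[:m] - pos_ranks) / n          # V10: per-positive
    v_neg = 1.0 - (ranks[m:] - neg_ranks) / m    # V01: per-negative
    return v_pos, v_neg


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong test for the AUC difference of two score vectors.

    Returns (ΔAUC, p) with ΔAUC = AUC(A) − AUC(B) and a two-sided normal
    p-value.  Identical scores give ΔAUC = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = labels, ~labels
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong test needs both classes present")

    va_pos, va_neg = _placements(scores_a[pos], scores_a[neg])
    vb_pos, vb_neg = _placements(scores_b[pos], scores_b[neg])
    auc_a, auc_b = va_pos.mean(), vb_pos.mean()
    delta = float(auc_a - auc_b)

    s_pos = np.cov(np.vstack([va_pos, vb_pos]))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]))
    var = (
        (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    )
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return delta, p


@dataclasses.dataclass
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    p: float | None  # vs. reference scores, if provided


def stratified_bootstrap(metric_fn, scores, labels, B: int = 2000,
                         seed: int = 0, ref_scores=None) -> BootstrapResult:
    """Stratified bootstrap: resample positives and negatives separately.

    Returns the point estimate, the percentile 95% CI, and — when
    ``ref_scores`` is given — a two-sided bootstrap p-value for the paired
    difference metric(scores) − metric(ref_scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("stratified bootstrap needs both classes")

    point = float(metric_fn(scores, labels))
    ref = None if ref_scores is None else np.asarray(ref_scores, dtype=float)
    point_delta = None if ref is None else point - float(metric_fn(ref, labels))

    stats = np.empty(B)
    deltas = np.empty(B) if ref is not None else None
    for b in range(B):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        stats[b] = metric_fn(scores[idx], labels[idx])
        if ref is not None:
            deltas[b] = stats[b] - metric_fn(ref[idx], labels[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    p = None
    if ref is not None:
        # two-sided: how often the resampled difference crosses zero
        frac = min(np.mean(deltas <= 0), np.mean(deltas >= 0))
        p = float(min(1.0, 2.0 * frac))
        del point_delta
    return BootstrapResult(point=point, ci_low=float(lo), ci_high=float(hi),
                           p=p)
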