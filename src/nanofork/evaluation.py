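"""Evaluation machinery: confusion counts, ROC sweeps, median profiles,
origin-distance distributions and chromosome pileups.

All metrics operate on per-thymidine (probability, truth) pairs pooled across
reads; balanced accuracy is the mean of sensitivity and specificity.  A BrdU
call at threshold ``t`` is ``probability > t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nanofork.detect import DetectRecord
from nanofork.forks import FeatureCall


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _pool(records: list[DetectRecord], truths: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if len(records) != len(truths):
        raise EvaluationError("records and truth label lists differ in length")
    probs, labels = [], []
    for rec, truth in zip(records, truths):
        truth = np.asarray(truth, dtype=bool)
        if truth.size != len(rec):
            raise EvaluationError(
                f"read {rec.read_id!r}: {len(rec)} probabilities but {truth.size} labels"
            )
        probs.append(rec.probabilities)
        labels.append(truth)
    return np.concatenate(probs), np.concatenate(labels)


def confusion_at_threshold(
    records: list[DetectRecord], truths: list[np.ndarray], threshold: float
) -> ConfusionCounts:
    """TP/FP/TN/FN over all evaluated thymidines at one threshold."""
    probs, labels = _pool(records, truths)
    calls = probs > threshold
    return ConfusionCounts(
        tp=int((calls & labels).sum()),
        fp=int((calls & ~labels).sum()),
        tn=int((~calls & ~labels).sum()),
        fn=int((~calls & labels).sum()),
    )


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(TPR + TNR) / 2; undefined denominators are an error, not silent zero."""
    if c.tp + c.fn == 0:
        raise EvaluationError("balanced accuracy undefined: no positive truth labels")
    if c.tn + c.fp == 0:
        raise EvaluationError("balanced accuracy undefined: no negative truth labels")
    tpr = c.tp / (c.tp + c.fn)
    tnr = c.tn / (c.tn + c.fp)
    return (tpr + tnr) / 2.0


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise EvaluationError("specificity undefined: no negative truth labels")
    return c.tn / (c.tn + c.fp)


def roc_curve(
    records: list[DetectRecord], truths: list[np.ndarray], n_thresholds: int = 101
) -> list[tuple[float, float, float]]:
    """(threshold, FPR, TPR) points sweeping thresholds over [0, 1].

    Thresholds are ``n_thresholds`` evenly spaced values plus the empirical
    probability set when that set is small (<= 10,000 distinct values), so
    the curve is exact on modest cohorts.  Requires both truth classes.
    """
    probs, labels = _pool(records, truths)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both truth classes")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    distinct = np.unique(probs)
    if distinct.size <= 10_000:
        thresholds = np.unique(np.concatenate([thresholds, distinct]))
    # vectorised sweep via sorting
    order = np.argsort(probs, kind="stable")
    sorted_probs = probs[order]
    pos_cum = np.concatenate([[0], np.cumsum(labels[order])])
    neg_cum = np.concatenate([[0], np.cumsum(~labels[order])])
    idx = np.searchsorted(sorted_probs, thresholds, side="right")
    tp = n_pos - pos_cum[idx]
    fp = n_neg - neg_cum[idx]
    return [
        (float(t), float(f / n_neg), float(p / n_pos))
        for t, f, p in zip(thresholds, fp, tp)
    ]


def roc_auc(points: list[tuple[float, float, float]]) -> float:
    """Trapezoidal area under a (threshold, FPR, TPR) curve."""
    pts = sorted((fpr, tpr) for _, fpr, tpr in points)
    pts = [(0.0, 0.0)] + pts + [(1.0, 1.0)]
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def median_profile(records: list[DetectRecord]) -> dict[int, float]:
    """Per-construct-position median BrdU probability over a cohort.

    All records must share one construct (contig); positions are reported
    1-based to match the primer-extension convention.
    """
    if not records:
        raise EvaluationError("empty cohort")
    contigs = {rec.contig for rec in records}
    if len(contigs) != 1:
        raise EvaluationError(f"records span multiple constructs: {sorted(contigs)}")
    by_pos: dict[int, list[float]] = {}
    for rec in records:
        for pos, prob in zip(rec.positions, rec.probabilities):
            by_pos.setdefault(int(pos) + 1, []).append(float(prob))
    return {pos: float(np.median(vals)) for pos, vals in sorted(by_pos.items())}


def origin_distance_distribution(
    calls: list[FeatureCall],
    known_origins: list[tuple[str, int, int]],
) -> tuple[list[float], int]:
    """Signed distance (bp) from each call midpoint to the nearest known origin.

    Distance is 0 when the call interval overlaps a known origin.  Calls on
    contigs absent from the known set are skipped and counted; their count is
    returned alongside the distances.
    """
    if not known_origins:
        raise EvaluationError("known origin set is empty")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in known_origins:
        by_contig.setdefault(contig, []).append((int(start), int(end)))
    distances = []
    skipped = 0
    for call in calls:
        origins = by_contig.get(call.contig)
        if origins is None:
            skipped += 1
            continue
        mid = (call.start + call.end) / 2.0
        best = None
        for start, end in origins:
            if call.end > start and call.start < end:
                best = 0.0
                break
            d = start - mid if mid < start else mid - (end - 1)
            signed = (start - mid) if mid < start else -(mid - (end - 1))
            if best is None or abs(signed) < abs(best):
                best = signed
        distances.append(float(best))
    return distances, skipped


def pileup(calls: list[FeatureCall], contig_length: int, bin_bp: int) -> np.ndarray:
    """Count of call intervals overlapping each ``bin_bp`` bin of a contig."""
    if bin_bp < 1:
        raise EvaluationError("bin_bp must be >= 1")
    n_bins = -(-contig_length // bin_bp)
    counts = np.zeros(n_bins, dtype=np.int64)
    for call in calls:
        first = max(call.start, 0) // bin_bp
        last = min(call.end - 1, contig_length - 1) // bin_bp
        if last >= first:
            counts[first : last + 1] += 1
    return counts
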