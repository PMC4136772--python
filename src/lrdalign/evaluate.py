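"""Threshold-sweep evaluation of aligner output against read truth.

Reads carry a ground-truth label (positive: sampled from the alignment
target; negative: contaminant) and the aligner's minimum distance.  A
read counts as aligned at threshold ``t`` iff its distance is finite
and ``<= t`` (a ``direction="higher"`` flag flips the comparison for
score-like measures where larger means better).  Sweeping ``t`` over
the distinct observed distances yields the precision/recall and ROC
curves; AUC, F-beta summaries and the TP/FN sequence-distance audit
are derived from them.

Reads the aligner produced no distance for are treated as distance
``+inf`` and are never aligned at any threshold.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .rankdist import edit_distance, hamming_distance, revcomp
from .simulate import SimulatedRead


@dataclass(frozen=True)
class LabeledResult:
    read_id: str
    positive: bool
    distance: float  # math.inf when the aligner produced nothing


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    tpr: float
    fpr: float


@dataclass(frozen=True)
class TpFnSummary:
    """Counts and mean Hamming/edit distances to the ground-truth
    substring for mapped (TP) and unmapped (FN) positive reads; a mean
    is ``None`` when its side is empty."""

    threshold: float
    n_tp: int
    n_fn: int
    tp_mean_hamming: float | None
    tp_mean_edit: float | None
    fn_mean_hamming: float | None
    fn_mean_edit: float | None


def _is_aligned(distance: float, threshold: float, direction: str) -> bool:
    if not math.isfinite(distance):
        return False
    return distance >= threshold if direction == "higher" else distance <= threshold


def confusion_at_threshold(
    results: list[LabeledResult], threshold: float, direction: str = "lower"
) -> CurvePoint:
    """Confusion counts and rates at one distance threshold.

    Precision is the proportion of aligned reads that are positive;
    recall (= TPR) the proportion of positive reads aligned.  Precision
    is 0 by convention when nothing aligns.
    """
    tp = fp = fn = tn = 0
    for r in results:
        aligned = _is_aligned(r.distance, threshold, direction)
        if r.positive:
            tp += aligned
            fn += not aligned
        else:
            fp += aligned
            tn += not aligned
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return CurvePoint(threshold, tp, fp, fn, tn, precision, recall, recall, fpr)


def pr_curve(
    results: list[LabeledResult], direction: str = "lower"
) -> list[CurvePoint]:
    """One point per distinct finite observed distance, plus a sentinel
    threshold below (above, for ``direction="higher"``) every distance
    at which nothing aligns."""
    finite = sorted({r.distance for r in results if math.isfinite(r.distance)})
    sentinel = math.inf if direction == "higher" else -math.inf
    thresholds = [sentinel] + (finite[::-1] if direction == "higher" else finite)
    return [confusion_at_threshold(results, t, direction) for t in thresholds]


def roc_auc(results: list[LabeledResult], direction: str = "lower") -> float:
    """Area under the ROC curve (trapezoidal, diagonal segments on ties).

    Requires at least one positive and one negative read.
    """
    labels = np.array([r.positive for r in results], dtype=int)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both a positive and a negative read")
    d = np.array([r.distance for r in results], dtype=float)
    finite = d[np.isfinite(d)]
    ceiling = (finite.max() if finite.size else 0.0) + 1.0
    d = np.where(np.isfinite(d), d, ceiling)  # never-aligned reads rank worst
    scores = d if direction == "higher" else -d
    return float(roc_auc_score(labels, scores))


def f_beta(precision: float, recall: float, beta: float = 1.0) -> float:
    """F-measure ``(1+beta^2) P R / (beta^2 P + R)``; 0 when P = R = 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def best_f_beta(curve: list[CurvePoint], beta: float = 1.0) -> float:
    """Best F-beta score attained anywhere on the curve."""
    if not curve:
        raise ValueError("empty curve")
    return max(f_beta(p.precision, p.recall, beta) for p in curve)


def recall_at_best_precision(curve: list[CurvePoint]) -> tuple[float, float]:
    """(recall, precision): the best recall among points attaining the
    curve's maximal precision."""
    if not curve:
        raise ValueError("empty curve")
    best_p = max(p.precision for p in curve)
    best_r = max(p.recall for p in curve if p.precision == best_p)
    return best_r, best_p


def max_recall(curve: list[CurvePoint]) -> float:
    """Largest recall attained anywhere on the curve."""
    if not curve:
        raise ValueError("empty curve")
    return max(p.recall for p in curve)


@functools.lru_cache(maxsize=65536)
def _truth_distances(read: SimulatedRead) -> tuple[int, int]:
    bases = read.read.bases
    if read.strand == "-":
        bases = revcomp(bases)
    return (
        hamming_distance(bases, read.truth_substring),
        edit_distance(bases, read.truth_substring),
    )


def tp_fn_distance_metrics(
    results: list[LabeledResult],
    truth: dict[str, SimulatedRead],
    threshold: float,
    direction: str = "lower",
) -> TpFnSummary:
    """Audit positive reads at one threshold.

    Positive reads are partitioned into mapped (TP) and unmapped (FN);
    each side reports its count and its mean Hamming and edit distance
    between the read (re-complemented for reverse-strand reads) and the
    ground-truth substring it was sampled from.
    """
    tp_h: list[int] = []
    tp_e: list[int] = []
    fn_h: list[int] = []
    fn_e: list[int] = []
    for r in results:
        if not r.positive:
            continue
        if r.read_id not in truth:
            raise KeyError(f"no ground truth for read {r.read_id!r}")
        h, e = _truth_distances(truth[r.read_id])
        if _is_aligned(r.distance, threshold, direction):
            tp_h.append(h)
            tp_e.append(e)
        else:
            fn_h.append(h)
            fn_e.append(e)

    def mean(v: list[int]) -> float | None:
        return float(np.mean(v)) if v else None

    return TpFnSummary(
        threshold, len(tp_h), len(fn_h),
        mean(tp_h), mean(tp_e), mean(fn_h), mean(fn_e),
    )
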