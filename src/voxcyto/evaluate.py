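"""Detection and segmentation accuracy metrics.

Detections are scored against annotated centres with the radius rule: a
detection is a true positive if it lies within 1.5 μm (about one cell
radius) of an annotated centre and no other detection is closer to that
centre; other detections within the radius are false positives;
annotated centres with no detection within the radius are false
negatives. Average precision (AP) is the area under the
precision-recall curve swept over all detector thresholds
(un-interpolated step sum over recall increments).

Segmentations are scored by the Jaccard index (intersection over union
of voxel masks) aggregated through an optimal one-to-one matching that
maximizes total overlap; AO is the mean Jaccard over matched pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .stacks import DetectionSet

__all__ = [
    "MatchResult",
    "OverlapResult",
    "match_detections",
    "average_precision",
    "jaccard",
    "segmentation_ao",
]

DEFAULT_MATCH_RADIUS_UM = 1.5


@dataclass
class MatchResult:
    tp: list  # (det index, truth index) pairs
    fp: list  # det indices
    fn: list  # truth indices

    @property
    def precision(self) -> float:
        n = len(self.tp) + len(self.fp)
        return len(self.tp) / n if n else 0.0

    @property
    def recall(self) -> float:
        n = len(self.tp) + len(self.fn)
        return len(self.tp) / n if n else 0.0


def match_detections(
    det_coords_um: np.ndarray,
    truth_coords_um: np.ndarray,
    radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> MatchResult:
    """One-to-one matching under the radius rule.

    Each annotated centre takes its nearest detection within
    ``radius_um``; pairs are resolved greedily by ascending distance so
    a detection matches at most one centre. All other detections are
    false positives; unmatched centres are false negatives.
    """
    det = np.atleast_2d(np.asarray(det_coords_um, dtype=float))
    truth = np.atleast_2d(np.asarray(truth_coords_um, dtype=float))
    if det.size == 0:
        return MatchResult([], [], list(range(len(truth))))
    if truth.size == 0:
        return MatchResult([], list(range(len(det))), [])
    d = cdist(truth, det)
    pairs = [
        (d[t, j], t, j)
        for t in range(len(truth))
        for j in range(len(det))
        if d[t, j] <= radius_um
    ]
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = []
    for dist, t, j in pairs:
        if t in used_t or j in used_d:
            continue
        used_t.add(t)
        used_d.add(j)
        tp.append((j, t))
    fp = [j for j in range(len(det)) if j not in used_d]
    fn = [t for t in range(len(truth)) if t not in used_t]
    return MatchResult(tp, fp, fn)


def precision_recall_curve(
    dets: DetectionSet,
    truth_coords_um: np.ndarray,
    radius_um: float = DEFAULT_MATCH_RADIUS_UM,
):
    """(precision, recall, threshold) arrays over all distinct scores,
    swept from the strictest threshold down."""
    truth = np.atleast_2d(np.asarray(truth_coords_um, dtype=float))
    if truth.size == 0:
        raise ValueError("average precision is undefined for empty truth")
    thresholds = np.unique(dets.scores)[::-1]
    precisions, recalls = [], []
    for tau in thresholds:
        keep = dets.scores >= tau
        res = match_detections(dets.coords_um[keep], truth, radius_um)
        precisions.append(res.precision)
        recalls.append(res.recall)
    return np.asarray(precisions), np.asarray(recalls), thresholds


def average_precision(
    dets: DetectionSet,
    truth_coords_um: np.ndarray,
    radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> float:
    """Area under the precision-recall curve (un-interpolated).

    AP = sum over operating points of precision times the recall
    increment, invariant to strictly monotone score transformations.
    """
    if len(dets) == 0:
        return 0.0
    p, r, _ = precision_recall_curve(dets, truth_coords_um, radius_um)
    prev = 0.0
    ap = 0.0
    for pi, ri in zip(p, r):
        ap += pi * (ri - prev)
        prev = ri
    return float(ap)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean masks; 0 if both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 0")
        return 0.0
    return np.count_nonzero(a & b) / union


@dataclass
class OverlapResult:
    pairs: list  # (label_a, label_b, jaccard) over the optimal matching
    ao: float
    precision: float
    recall: float
    jaccard_matrix: np.ndarray = field(repr=False, default=None)
    labels_a: np.ndarray = field(repr=False, default=None)
    labels_b: np.ndarray = field(repr=False, default=None)


def _pairwise_jaccard(labels_a: np.ndarray, labels_b: np.ndarray):
    la = np.unique(labels_a)
    la = la[la > 0]
    lb = np.unique(labels_b)
    lb = lb[lb > 0]
    if la.size == 0 or lb.size == 0:
        return la, lb, np.zeros((la.size, lb.size))
    # joint histogram of (a, b) label pairs
    ia = np.searchsorted(la, labels_a.ravel())
    ib = np.searchsorted(lb, labels_b.ravel())
    valid = (labels_a.ravel() > 0) & (labels_b.ravel() > 0)
    inter = np.zeros((la.size, lb.size))
    np.add.at(inter, (ia[valid], ib[valid]), 1)
    size_a = np.array([(labels_a == v).sum() for v in la], dtype=float)
    size_b = np.array([(labels_b == v).sum() for v in lb], dtype=float)
    union = size_a[:, None] + size_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    return la, lb, jac


def segmentation_ao(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    match_threshold: float = 0.5,
) -> OverlapResult:
    """Average overlap via optimal one-to-one matching.

    The assignment maximizes total Jaccard; pairs with zero overlap are
    not considered matched. AO is the mean Jaccard over matched pairs;
    segment-level precision (resp. recall) counts matched pairs with
    Jaccard >= ``match_threshold`` over the number of segments of A
    (resp. B).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label volume shape mismatch")
    la, lb, jac = _pairwise_jaccard(labels_a, labels_b)
    pairs = []
    if jac.size:
        rows, cols = linear_sum_assignment(-jac)
        for r, c in zip(rows, cols):
            if jac[r, c] > 0:
                pairs.append((int(la[r]), int(lb[c]), float(jac[r, c])))
    ao = float(np.mean([p[2] for p in pairs])) if pairs else 0.0
    good = sum(1 for p in pairs if p[2] >= match_threshold)
    precision = good / la.size if la.size else 0.0
    recall = good / lb.size if lb.size else 0.0
    return OverlapResult(pairs, ao, precision, recall, jac, la, lb)
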