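"""Instance-matching metrics between predicted and reference label volumes.

Objects are matched one-to-one by intersection-over-union (IoU) at a
configurable threshold, greedily in decreasing-IoU order; precision,
recall and F1 follow from the match counts.  Used to validate segmentation
against the synthetic generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse


@dataclass
class MatchResult:
    n_truth: int
    n_pred: int
    n_matched: int
    precision: float
    recall: float
    f1: float
    pairs: list[tuple[int, int, float]]  # (truth label, pred label, IoU)


def _pair_ious(truth: np.ndarray, pred: np.ndarray):
    """Sparse contingency of voxel overlaps -> per-pair IoU."""
    t = truth.ravel()
    p = pred.ravel()
    fg = (t > 0) | (p > 0)
    t, p = t[fg], p[fg]
    nt, npred = int(truth.max()) + 1, int(pred.max()) + 1
    cont = sparse.coo_matrix(
        (np.ones(len(t), dtype=np.int64), (t, p)), shape=(nt, npred)
    ).tocsr()
    t_sizes = np.asarray(cont.sum(axis=1)).ravel()
    p_sizes = np.asarray(cont.sum(axis=0)).ravel()
    cont = cont.tocoo()
    out = []
    for ti, pi, inter in zip(cont.row, cont.col, cont.data):
        if ti == 0 or pi == 0:
            continue
        union = t_sizes[ti] + p_sizes[pi] - inter
        out.append((int(ti), int(pi), float(inter / union)))
    return out


def match_instances(
    truth_labels: np.ndarray, pred_labels: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """One-to-one IoU matching of predicted objects to reference objects."""
    truth_ids = np.unique(truth_labels)
    pred_ids = np.unique(pred_labels)
    n_truth = int((truth_ids > 0).sum())
    n_pred = int((pred_ids > 0).sum())
    pairs = sorted(_pair_ious(truth_labels, pred_labels), key=lambda r: -r[2])
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = []
    for ti, pi, iou in pairs:
        if iou < iou_threshold:
            break
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matched.append((ti, pi, iou))
    n = len(matched)
    precision = n / n_pred if n_pred else 0.0
    recall = n / n_truth if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return MatchResult(n_truth=n_truth, n_pred=n_pred, n_matched=n,
                       precision=precision, recall=recall, f1=f1, pairs=matched)
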