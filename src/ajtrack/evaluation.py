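"""Detection and tracking performance metrics.

Vertex detections are scored by one-to-one matching against annotated
positions within a radius (default 2 voxels); matched pairs are true
positives, surplus detections false positives, missed annotations false
negatives.  Precision, Recall and the F1 measure summarise the counts;
sweeping the detection threshold yields Precision-Recall curves.

Tracking is scored as per-cell label prediction over each frame pair: a cell
either continues (association), terminates (leave or apoptosis) or divides
(mitosis), and new cells are created (enter or mitosis child).  The AF1
score is the harmonic mean of the four per-category F1 measures
(association, creation, termination, mitosis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "MatchParams",
    "match_vertices",
    "match_edges",
    "precision_recall_f1",
    "pr_sweep",
    "event_f1_scores",
    "af1",
]


@dataclass
class MatchParams:
    """Maximum detection-to-annotation distance counted as a hit (voxels)."""

    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("match radius must be > 0")


def match_vertices(
    detected: np.ndarray, truth: np.ndarray, params: MatchParams | None = None
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one minimum-cost matching of detections to annotations.

    Positions are in voxel coordinates; only pairs closer than the match
    radius may be matched.  Returns ``(tp, fp, fn, matching)`` where
    ``matching`` lists (detected index, truth index) pairs.
    """
    params = params or MatchParams()
    det = np.atleast_2d(np.asarray(detected, dtype=float)) if np.size(detected) else np.empty((0, 3))
    tru = np.atleast_2d(np.asarray(truth, dtype=float)) if np.size(truth) else np.empty((0, 3))
    nd, nt = det.shape[0], tru.shape[0]
    if nd == 0 or nt == 0:
        return 0, nd, nt, []
    dist = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    big = params.radius * 1e6 + 1.0
    cost = np.where(dist <= params.radius, dist, big)
    rows, cols = linear_sum_assignment(cost)
    matching = [(int(r), int(c)) for r, c in zip(rows, cols) if dist[r, c] <= params.radius]
    tp = len(matching)
    return tp, nd - tp, nt - tp, matching


def match_edges(
    detected_edges: list[tuple[int, int]],
    truth_edges: list[tuple[int, int]],
    vertex_matching: list[tuple[int, int]],
) -> tuple[int, int, int]:
    """Edge-level counts given a vertex correspondence.

    A detected edge is a true positive iff both endpoints matched annotated
    vertices and those two annotated vertices are connected in the truth.
    """
    det_to_truth = dict(vertex_matching)
    truth_set = {(min(u, v), max(u, v)) for u, v in truth_edges}
    tp = 0
    matched_truth: set[tuple[int, int]] = set()
    for u, v in detected_edges:
        if u in det_to_truth and v in det_to_truth:
            e = (min(det_to_truth[u], det_to_truth[v]), max(det_to_truth[u], det_to_truth[v]))
            if e in truth_set and e not in matched_truth:
                tp += 1
                matched_truth.add(e)
                continue
    fp = len(detected_edges) - tp
    fn = len(truth_set) - tp
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, Recall and their harmonic mean.

    A zero denominator yields 0 for the affected metric (logged, since a
    detector with no true positives is degenerate rather than undefined).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp == 0 and (fp > 0 or fn > 0):
        logger.info("tp=0 with fp=%d fn=%d: metrics defined as 0", fp, fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def pr_sweep(
    candidates: np.ndarray,
    scores: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray,
    params: MatchParams | None = None,
) -> list[dict[str, float]]:
    """Precision-Recall curve over detection thresholds.

    ``candidates`` are candidate vertex positions (voxels) with detection
    ``scores``; at each threshold only candidates scoring >= it survive and
    are re-matched against the truth.  Recall is non-increasing in the
    threshold because raising it never adds a detection.
    """
    out = []
    for thr in thresholds:
        det = candidates[scores >= thr] if len(candidates) else candidates
        tp, fp, fn, _ = match_vertices(det, truth, params)
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        out.append({"threshold": float(thr), "precision": p, "recall": r, "f1": f1,
                    "tp": tp, "fp": fp, "fn": fn})
    return out


# ---------------------------------------------------------------------------
# tracking events
# ---------------------------------------------------------------------------

_CATEGORIES = ("association", "creation", "termination", "mitosis")


def _labels_from_hypotheses(hypotheses) -> tuple[dict, dict, set, set]:
    """Per-cell event labels from a frame-pair solution.

    Returns (association target per t-cell, termination kind per t-cell,
    created t+1 cells, t-cells that divided).
    """
    assoc: dict[int, int] = {}
    term: dict[int, str] = {}
    created: set[int] = set()
    divided: set[int] = set()
    for h in hypotheses:
        if h.kind == "association":
            assoc[h.source] = h.targets[0]
        elif h.kind in ("leave", "apoptosis"):
            term[h.source] = h.kind
        elif h.kind == "enter":
            created.add(h.targets[0])
        elif h.kind == "mitosis":
            divided.add(h.source)
            created.update(h.targets)
    return assoc, term, created, divided


def event_f1_scores(predicted, truth) -> dict[str, float]:
    """Per-category F1 over one or more frame-pair solutions.

    ``predicted`` and ``truth`` are lists (one entry per frame pair) of
    hypothesis lists covering the same cells.  Categories: association
    (correct target required), creation (enter or mitosis child), termination
    (leave or apoptosis), mitosis (correct sibling pair required).  A
    category absent from both truth and prediction scores 1 (vacuously
    perfect; logged).
    """
    counts = {k: [0, 0, 0] for k in _CATEGORIES}  # tp, fp, fn
    for pred_sol, true_sol in zip(predicted, truth):
        p_assoc, p_term, p_created, p_div = _labels_from_hypotheses(pred_sol)
        t_assoc, t_term, t_created, t_div = _labels_from_hypotheses(true_sol)
        for src, tgt in p_assoc.items():
            if t_assoc.get(src) == tgt:
                counts["association"][0] += 1
            else:
                counts["association"][1] += 1
        counts["association"][2] += sum(
            1 for src, tgt in t_assoc.items() if p_assoc.get(src) != tgt
        )
        counts["creation"][0] += len(p_created & t_created)
        counts["creation"][1] += len(p_created - t_created)
        counts["creation"][2] += len(t_created - p_created)
        counts["termination"][0] += len(set(p_term) & set(t_term))
        counts["termination"][1] += len(set(p_term) - set(t_term))
        counts["termination"][2] += len(set(t_term) - set(p_term))
        p_mit = {(s, tuple(sorted(h.targets))) for h in pred_sol for s in [h.source]
                 if h.kind == "mitosis"}
        t_mit = {(s, tuple(sorted(h.targets))) for h in true_sol for s in [h.source]
                 if h.kind == "mitosis"}
        counts["mitosis"][0] += len(p_mit & t_mit)
        counts["mitosis"][1] += len(p_mit - t_mit)
        counts["mitosis"][2] += len(t_mit - p_mit)
    scores = {}
    for k, (tp, fp, fn) in counts.items():
        if tp + fp + fn == 0:
            logger.info("event category %r absent from truth and prediction: F1 := 1", k)
            scores[k] = 1.0
        else:
            scores[k] = precision_recall_f1(tp, fp, fn)[2]
    return scores


def af1(f1_scores: dict[str, float] | tuple[float, float, float, float]) -> float:
    """Harmonic mean of the four per-event F1 measures.

    ``AF1 = 4 / (F1_assoc^-1 + F1_creation^-1 + F1_termination^-1 +
    F1_mitosis^-1)``; zero if any component is zero.
    """
    if isinstance(f1_scores, dict):
        vals = [f1_scores[k] for k in _CATEGORIES]
    else:
        vals = list(f1_scores)
    if len(vals) != 4:
        raise ValueError("AF1 needs exactly four component F1 scores")
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("F1 components must lie in [0, 1]")
    if any(v == 0 for v in vals):
        return 0.0
    return 4.0 / sum(1.0 / v for v in vals)
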