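"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import matthews_corrcoef


def flood_fill_components(binary: np.ndarray):
    """8-connected component labeling by explicit flood fill.

    Returns a list of dicts with ``area`` and half-open ``bbox``
    (top, left, bottom, right), one per component.
    """
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or visited[r0, c0]:
                continue
            stack = [(r0, c0)]
            visited[r0, c0] = True
            pixels = []
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h and 0 <= cc < w
                            and binary[rr, cc] and not visited[rr, cc]
                        ):
                            visited[rr, cc] = True
                            stack.append((rr, cc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            comps.append(
                {
                    "area": len(pixels),
                    "bbox": (min(rows), min(cols), max(rows) + 1, max(cols) + 1),
                }
            )
    return comps


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the pairwise Mann-Whitney statistic U/(n1·n0), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def brute_force_threshold(scores, labels):
    """Exhaustive MCC sweep over every candidate threshold.

    Candidates are 0, 1 and midpoints between consecutive distinct sorted
    scores; decision rule is score ≥ threshold ⇒ positive; ties in MCC go
    to the smallest threshold. MCC is computed by sklearn, independently
    of the package's own formula.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]))
    best_thr, best_mcc = None, -np.inf
    for thr in candidates:
        pred = (scores >= thr).astype(int)
        value = matthews_corrcoef(labels, pred)
        if value > best_mcc:
            best_thr, best_mcc = float(thr), float(value)
    return best_thr, best_mcc


def enumerate_confusion_matrices(
    n: int, sensitivity: float, specificity: float, accuracy_pct: int
):
    """All non-negative integer confusion matrices on ``n`` samples whose
    sensitivity and specificity match exactly and whose accuracy rounds to
    the given whole percent. Returns (tp, fp, fn, tn) tuples."""
    out = []
    for pos in range(1, n):  # pos = TP + FN, need both classes present
        neg = n - pos
        tp = sensitivity * pos
        tn = specificity * neg
        if abs(tp - round(tp)) > 1e-9 or abs(tn - round(tn)) > 1e-9:
            continue
        tp, tn = int(round(tp)), int(round(tn))
        if round((tp + tn) / n * 100) != accuracy_pct:
            continue
        out.append((tp, neg - tn, pos - tp, tn))
    return out
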