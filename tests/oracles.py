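"""Independent reference implementations used only by the tests."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def sw_bruteforce(q: np.ndarray, s: np.ndarray, s_max: float, m0: float, gap: float):
    """Best local alignment by exhaustive enumeration.

    Enumerates every non-empty set of aligned index pairs that is strictly
    increasing in both sequences; the score is the sum of substitution
    scores minus ``gap`` per skipped position strictly between consecutive
    aligned pairs (local alignment: flanking positions are free).
    Feasible only for tiny profiles (choose(len q, k) * choose(len s, k)
    alignments); returns ``(best_score, best_pairs)`` with 0.0/[] when
    every alignment scores <= 0.
    """
    nq, ns = len(q), len(s)
    sigma = s_max - np.abs(q[:, None] - s[None, :]) / m0
    best_score, best_pairs = 0.0, []
    for k in range(1, min(nq, ns) + 1):
        for rows in combinations(range(nq), k):
            for cols in combinations(range(ns), k):
                score = sigma[list(rows), list(cols)].sum()
                for (a0, b0), (a1, b1) in zip(zip(rows, cols), zip(rows[1:], cols[1:])):
                    score -= gap * ((a1 - a0 - 1) + (b1 - b0 - 1))
                if score > best_score + 1e-12:
                    best_score = score
                    best_pairs = list(zip(rows, cols))
    return best_score, best_pairs


def average_precision_step_area(flags) -> float:
    """AP as the area under the uninterpolated precision-recall steps."""
    total = sum(flags)
    area = 0.0
    tp = 0
    prev_recall = 0.0
    for rank, rel in enumerate(flags, start=1):
        if rel:
            tp += 1
            recall = tp / total
            area += (recall - prev_recall) * (tp / rank)
            prev_recall = recall
    return area
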