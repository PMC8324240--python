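"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations (and any
shared code paths) so they can serve as cross-checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_auroc(scores, labels) -> float:
    """O(n^2) pairwise concordance count."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s1 in pos:
        for s0 in neg:
            if s1 > s0:
                total += 1.0
            elif s1 == s0:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_confusion(pred, outcome):
    tp = fp = tn = fn = 0
    for p, o in zip(pred, outcome):
        if p and o:
            tp += 1
        elif p and not o:
            fp += 1
        elif not p and o:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def gini(counts) -> float:
    n = sum(counts)
    if n == 0:
        return 0.0
    return 1.0 - sum((c / n) ** 2 for c in counts)


def brute_force_best_split_cost(x, y, min_leaf=1):
    """Minimum total weighted child Gini over every (feature, threshold).

    Enumerates midpoints between all consecutive distinct values of every
    feature; returns the minimal n_L*G(L) + n_R*G(R).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n, p = x.shape
    best = None
    for j in range(p):
        for thr in np.unique(x[:, j]):
            left = x[:, j] <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_leaf or nr < min_leaf or nr == 0:
                continue
            cost = nl * gini([np.sum(y[left] == c) for c in np.unique(y)]) + nr * gini(
                [np.sum(y[~left] == c) for c in np.unique(y)]
            )
            if best is None or cost < best:
                best = cost
    return best
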