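"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions with plain loops and
dictionaries, deliberately sharing no code with ``nitrack.mrmr`` beyond the
published discretization and tie rules.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

TIE_TOL = 1e-12


def mi_bruteforce(a, b) -> float:
    """Plug-in mutual information (nats) from explicit joint counts."""
    a = list(a)
    b = list(b)
    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * math.log(pxy / ((pa[x] / n) * (pb[y] / n)))
    return total


def discretize_bruteforce(column, n_bins: int = 3):
    """Equal-frequency bin codes via interior quantile edges."""
    edges = np.quantile(np.asarray(column, float), np.linspace(0, 1, n_bins + 1)[1:-1])
    return [int(np.searchsorted(edges, v, side="right")) for v in column]


def mrmr_bruteforce(X: np.ndarray, y, k: int, n_bins: int = 3) -> list[int]:
    """Greedy MID-mRMR recomputing every MI term from scratch each step.

    Tie rule: scores within a small relative tolerance of the maximum are
    tied, lowest feature index wins.
    """
    p = X.shape[1]
    binned = [discretize_bruteforce(X[:, j], n_bins) for j in range(p)]
    y = list(y)
    relevance = [mi_bruteforce(binned[j], y) for j in range(p)]

    selected: list[int] = []
    while len(selected) < k:
        best_score, scores = -np.inf, {}
        for j in range(p):
            if j in selected:
                continue
            if selected:
                red = sum(mi_bruteforce(binned[j], binned[s]) for s in selected)
                score = relevance[j] - red / len(selected)
            else:
                score = relevance[j]
            scores[j] = score
            best_score = max(best_score, score)
        tol = TIE_TOL * max(1.0, abs(best_score))
        pick = min(j for j, s in scores.items() if s >= best_score - tol)
        selected.append(pick)
    return selected
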