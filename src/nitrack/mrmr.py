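"""Greedy minimum-redundancy maximum-relevance (mRMR) feature selection.

MID ("difference") criterion: the first feature maximizes mutual
information with the class; each subsequent pick maximizes

    I(f; class) - mean_{s in selected} I(f; s)

Mutual information is estimated on a discretized copy of the features
(equal-frequency binning, 3 bins by default).  Selection is fully
deterministic: score ties (within a small relative tolerance, so that
float summation order cannot flip a pick) go to the lowest feature index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["discretize", "mutual_information", "mrmr_select"]

#: relative tolerance treating two scores as tied (lowest index wins)
TIE_TOL = 1e-12


def discretize(X: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning per column; returns int codes in [0, n_bins).

    Bin edges are interior quantiles; duplicate edges (heavily tied or
    constant columns) simply produce fewer occupied bins.
    """
    X = np.asarray(X, dtype=float)
    qs = np.quantile(X, np.linspace(0, 1, n_bins + 1)[1:-1], axis=0)
    out = np.zeros(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        out[:, j] = np.searchsorted(qs[:, j], X[:, j], side="right")
    return out


def _entropy_from_counts(counts: np.ndarray, axis=None) -> np.ndarray:
    n = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
        term = np.where(counts > 0, p * np.log(p), 0.0)
    return -term.sum(axis=axis)


def mutual_information(a: np.ndarray, b: np.ndarray, n_levels: int) -> float:
    """Plug-in MI (nats) between two integer-coded variables."""
    joint = np.zeros((n_levels, n_levels))
    np.add.at(joint, (a, b), 1.0)
    ha = _entropy_from_counts(joint.sum(axis=1))
    hb = _entropy_from_counts(joint.sum(axis=0))
    hab = _entropy_from_counts(joint.ravel())
    return float(ha + hb - hab)


def _relevance(D: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """I(f; class) for every column of the binned matrix, vectorized."""
    n, p = D.shape
    n_classes = int(y.max()) + 1
    flat = (np.arange(p)[None, :] * (n_bins * n_classes) + D * n_classes + y[:, None])
    counts = np.bincount(flat.ravel(), minlength=p * n_bins * n_classes).reshape(
        p, n_bins, n_classes
    ).astype(float)
    h_f = _entropy_from_counts(counts.sum(axis=2), axis=1)
    h_y = _entropy_from_counts(counts.sum(axis=1), axis=1)
    h_fy = _entropy_from_counts(counts.reshape(p, -1), axis=1)
    return h_f + h_y - h_fy


def _redundancy_with(D: np.ndarray, s: np.ndarray, n_bins: int) -> np.ndarray:
    """I(f; s) of one selected column against every column, vectorized."""
    n, p = D.shape
    flat = np.arange(p)[None, :] * (n_bins * n_bins) + D * n_bins + s[:, None]
    counts = np.bincount(flat.ravel(), minlength=p * n_bins * n_bins).reshape(
        p, n_bins, n_bins
    ).astype(float)
    h_f = _entropy_from_counts(counts.sum(axis=2), axis=1)
    h_s = _entropy_from_counts(counts.sum(axis=1), axis=1)
    h_fs = _entropy_from_counts(counts.reshape(p, -1), axis=1)
    return h_f + h_s - h_fs


def _argmax_tied_low(scores: np.ndarray) -> int:
    best = scores.max()
    tol = TIE_TOL * max(1.0, abs(best))
    return int(np.flatnonzero(scores >= best - tol)[0])


def mrmr_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    k: int = 10,
    n_bins: int = 3,
) -> list:
    """Select ``k`` features by greedy MID-mRMR.

    Returns feature names when ``X`` is a DataFrame, else column indices.
    Deterministic in the input (row order irrelevant).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("mRMR needs both classes present")
    p = Xv.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds feature count {p}")

    D = discretize(Xv, n_bins)
    y_codes = (y == y.max()).astype(np.int64) if y.dtype.kind not in "iu" else y.astype(np.int64)
    rel = _relevance(D, y_codes, n_bins)

    selected: list[int] = []
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for step in range(k):
        if step == 0:
            scores = rel.copy()
        else:
            scores = rel - red_sum / step
        scores[~available] = -np.inf
        pick = _argmax_tied_low(scores)
        selected.append(pick)
        available[pick] = False
        if step < k - 1:
            red_sum += _redundancy_with(D, D[:, pick], n_bins)

    return [names[i] for i in selected] if names is not None else selected
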