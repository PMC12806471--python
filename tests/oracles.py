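"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (brute-force
enumeration, plain dynamic programming, closed forms) and never calls into
:mod:`hetdti`'s own computational paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def sw_bruteforce_linear(a: str, b: str, score, gap: float) -> float:
    """Best local-alignment score by enumerating all monotone matchings.

    Valid for linear gap penalties W_k = gap * k: a local alignment is a
    non-empty monotone matching between positions of ``a`` and ``b``; its
    score is the sum of substitution scores minus ``gap`` times the number
    of unmatched positions lying strictly inside the matched span on either
    sequence (terminal gaps are free in local alignment). The best score is
    the max over all matchings, floored at 0.
    """
    n, m = len(a), len(b)
    h = np.array([[score(x, y) for y in b] for x in a], dtype=float)
    best = 0.0
    for k in range(1, min(n, m) + 1):
        a_combos = np.array(list(combinations(range(n), k)))
        b_combos = np.array(list(combinations(range(m), k)))
        s = np.zeros((len(a_combos), len(b_combos)))
        for t in range(k):
            s += h[a_combos[:, t][:, None], b_combos[:, t][None, :]]
        gaps_a = (a_combos[:, -1] - a_combos[:, 0] + 1 - k)[:, None]
        gaps_b = (b_combos[:, -1] - b_combos[:, 0] + 1 - k)[None, :]
        s = s - gap * (gaps_a + gaps_b)
        best = max(best, float(s.max()))
    return best


def sw_dp_plain(a: str, b: str, score, gap_open: float, gap_extend: float) -> np.ndarray:
    """Plain-python Smith-Waterman DP with explicit max-over-gap-lengths.

    O(n*m*(n+m)); evaluates the recurrence literally, including the
    max over all gap lengths k with W_k = open + (k-1)*extend.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = [0.0, H[i - 1][j - 1] + score(a[i - 1], b[j - 1])]
            for k in range(1, i + 1):
                cand.append(H[i - k][j] - (gap_open + (k - 1) * gap_extend))
            for l in range(1, j + 1):
                cand.append(H[i][j - l] - (gap_open + (l - 1) * gap_extend))
            H[i][j] = max(cand)
    return np.array(H)


def roc_auc_paircount(scores, labels) -> float:
    """ROC-AUC by exhaustive positive x negative pair counting (ties = 1/2)."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pr_auc_threshold_enum(scores, labels) -> float:
    """PR step-curve area by enumerating every distinct score as threshold.

    Average-precision form: sum over descending thresholds of
    (recall_t - recall_{t-1}) * precision_t.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def gcn_dense_oracle(H: np.ndarray, F: np.ndarray, W: np.ndarray,
                     relu: bool = True) -> np.ndarray:
    """Hand-rolled dense GCN layer: sigma(D^-1/2 (I+H) D^-1/2 F W)."""
    Ht = np.eye(H.shape[0]) + H
    d = Ht.sum(axis=1)
    A = Ht / np.sqrt(np.outer(d, d))
    out = A @ F @ W
    return np.maximum(out, 0.0) if relu else out


def uniform_attention_oracle(H: np.ndarray, F: np.ndarray, W: np.ndarray,
                             relu: bool = True) -> np.ndarray:
    """GAT layer with zero attention vector and zero edge bias: every node
    averages W F_j uniformly over its off-diagonal neighborhood (self-only
    for isolated nodes)."""
    n = H.shape[0]
    U = F @ W
    out = np.zeros_like(U)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and H[i, j] > 0]
        if not nbrs:
            nbrs = [i]
        out[i] = U[nbrs].mean(axis=0)
    return np.maximum(out, 0.0) if relu else out


def cart_best_split_enum(X: np.ndarray, y: np.ndarray):
    """Exhaustive minimal weighted-Gini split over midpoint thresholds.

    Returns (feature, threshold, gini_index) or None. Ties break toward the
    lowest feature index, then lowest threshold.
    """
    n, d = X.shape

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.bincount(labels.astype(int)) / len(labels)
        return 1.0 - (p**2).sum()

    best = None
    for f in range(d):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            left = X[:, f] <= thr
            g = left.mean() * gini(y[left]) + (1 - left.mean()) * gini(y[~left])
            if best is None or g < best[2] - 1e-15:
                best = (f, thr, g)
    return best
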