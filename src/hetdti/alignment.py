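"""Smith-Waterman local sequence alignment.

The scoring recurrence fills ``SW(i, j)`` with the best score of a local
alignment ending at residues ``a_i``, ``b_j``:

    SW(i,j) = max( SW(i-1,j-1) + h(a_i, b_j),
                   max_{k>=1} SW(i-k, j) - W_k,
                   max_{l>=1} SW(i, j-l) - W_l,
                   0 )

with substitution score ``h`` and gap penalty ``W_k`` for a gap of length
``k``. Gap penalties are affine, ``W_k = open + (k-1) * extend`` (linear when
``open == extend``), which lets the max-over-k terms be carried incrementally
(Gotoh's recurrence). The numba kernel makes all-pairs protein comparisons
cheap at the dataset sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: residue alphabet used for integer encoding (20 standard + X for unknown)
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus an affine gap model.

    ``matrix[i, j]`` scores aligning ``ALPHABET[i]`` with ``ALPHABET[j]``
    and must be symmetric. ``gap_penalty(k) = gap_open + (k-1)*gap_extend``
    for k >= 1, and 0 for an empty gap.
    """

    matrix: np.ndarray
    gap_open: float = 10.0
    gap_extend: float = 10.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"substitution matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        object.__setattr__(self, "matrix", m)

    def substitution(self, a: str, b: str) -> float:
        """h(a, b) for two single residues (unknowns map to X)."""
        ia = _CHAR_INDEX.get(a, _CHAR_INDEX["X"])
        ib = _CHAR_INDEX.get(b, _CHAR_INDEX["X"])
        return float(self.matrix[ia, ib])

    def gap_penalty(self, k: int) -> float:
        """W_k, the penalty for a gap of length k (nondecreasing, W_0 = 0)."""
        if k <= 0:
            return 0.0
        return self.gap_open + (k - 1) * self.gap_extend

    @classmethod
    def from_named_matrix(cls, name: str, gap_open: float = 10.0,
                          gap_extend: float | None = None) -> "AlignmentScoring":
        """Build a scoring scheme from a named substitution matrix (e.g. BLOSUM62)."""
        sub = substitution_matrices.load(name)
        m = np.empty((len(ALPHABET), len(ALPHABET)))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                m[i, j] = sub[a, b]
        if gap_extend is None:
            gap_extend = gap_open
        return cls(matrix=m, gap_open=gap_open, gap_extend=gap_extend)

    @classmethod
    def blosum62(cls, gap: float = 10.0) -> "AlignmentScoring":
        """BLOSUM62 with a linear gap penalty W_k = gap * k (the default)."""
        return cls.from_named_matrix("BLOSUM62", gap_open=gap, gap_extend=gap)

    @classmethod
    def identity(cls, match: float = 3.0, mismatch: float = -3.0,
                 gap: float = 2.0) -> "AlignmentScoring":
        """Simple +match/-mismatch scoring with a linear gap penalty."""
        m = np.full((len(ALPHABET), len(ALPHABET)), mismatch)
        np.fill_diagonal(m, match)
        return cls(matrix=m, gap_open=gap, gap_extend=gap)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a residue string to integer codes over :data:`ALPHABET`."""
    x = _CHAR_INDEX["X"]
    return np.fromiter((_CHAR_INDEX.get(c, x) for c in seq), dtype=np.int64, count=len(seq))


@njit(cache=True)
def _sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - numba kernel
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1))
    E = np.full(m + 1, -1e30)  # best vertical-gap score reaching row i, per column
    for i in range(1, n + 1):
        F = -1e30  # best horizontal-gap score in this row
        for j in range(1, m + 1):
            e = H[i - 1, j] - gap_open
            if E[j] - gap_extend > e:
                e = E[j] - gap_extend
            E[j] = e
            f = H[i, j - 1] - gap_open
            if F - gap_extend > f:
                f = F - gap_extend
            F = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H


def smith_waterman(
    a: str, b: str, scoring: AlignmentScoring
) -> tuple[float, np.ndarray]:
    """Best local-alignment score of two sequences plus the full score matrix.

    Returns ``(best_score, H)`` where ``H`` is the (n+1) x (m+1) scoring
    matrix with a zero first row/column and ``best_score = H.max() >= 0``.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires two nonempty sequences")
    H = _sw_fill(encode_sequence(a), encode_sequence(b), scoring.matrix,
                 scoring.gap_open, scoring.gap_extend)
    return float(H.max()), H


def pairwise_sw_scores(sequences: list[str], scoring: AlignmentScoring) -> np.ndarray:
    """All-pairs best Smith-Waterman scores (including each self-alignment)."""
    n = len(sequences)
    enc = [encode_sequence(s) for s in sequences]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            H = _sw_fill(enc[i], enc[j], scoring.matrix,
                         scoring.gap_open, scoring.gap_extend)
            out[i, j] = out[j, i] = H.max()
    return out
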