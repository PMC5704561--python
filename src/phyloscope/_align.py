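"""Profile-profile alignment engine.

Implements global (Needleman-Wunsch/Gotoh) and local (Smith-Waterman) affine
-gap dynamic programming over residue-frequency profiles, scoring columns by
the expected substitution score S(c1,c2) = sum_ab f1(a) f2(b) B(a,b) with
BLOSUM62. A gap run of length k costs open + (k-1)*extend (negative values).

One-hot profiles reduce the column score to the plain substitution score, so
the two-sequence case coincides exactly with classical sequence alignment.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
NT_ORDER = "ACGT"
NT_INDEX = {a: i for i, a in enumerate(NT_ORDER)}

GAP_OPEN = -11.0
GAP_EXTEND = -1.0

_NEG = -1e30


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in AA_ORDER."""
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = raw[a, b]
    return mat


BLOSUM62 = blosum62_matrix()
#: simple +1/-1 nucleotide matrix for completeness
NUC_MATRIX = np.where(np.eye(4, dtype=bool), 1.0, -1.0)


def column_frequencies(rows: Sequence[str], alphabet_index=AA_INDEX) -> np.ndarray:
    """Per-column residue frequencies over non-gap residues (rows of len L).

    All-gap columns yield zero rows. Unknown residues (e.g. X) are ignored.
    """
    if not rows:
        raise ValueError("no rows")
    length = len(rows[0])
    k = len(alphabet_index)
    counts = np.zeros((length, k))
    for row in rows:
        if len(row) != length:
            raise ValueError("ragged alignment rows")
        for pos, res in enumerate(row):
            idx = alphabet_index.get(res)
            if idx is not None:
                counts[pos, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return freqs


def column_scores(p: np.ndarray, q: np.ndarray, subs: np.ndarray = BLOSUM62) -> np.ndarray:
    return p @ subs @ q.T


def _global_fill(
    s: np.ndarray, open_: float, extend: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, m = s.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in second profile (consumes first)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in first profile (consumes second)
    M[0, 0] = 0.0
    if m >= 1:
        Y[0, 1:] = open_ + extend * np.arange(m)
    cols = np.arange(m + 1)
    for i in range(1, n + 1):
        X[i, 0] = open_ + extend * (i - 1)
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = s[i - 1] + best_prev[:-1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] + open_, X[i - 1, 1:] + extend)
        # Y[i,j] = max(M[i,j-1]+open, Y[i,j-1]+extend): closed-form scan
        a = M[i] + open_ - extend * cols
        c = np.maximum.accumulate(a)
        Y[i, 1:] = extend * (cols[1:] - 1) + c[:-1]
    return M, X, Y


def global_profile_align(
    p: np.ndarray,
    q: np.ndarray,
    subs: np.ndarray = BLOSUM62,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Tuple[float, List[Tuple[int, int]]]:
    """Globally align two profiles.

    Returns the optimal score and the alignment path as a list of
    ``(i, j)`` moves where each element is a column pair: ``(i, -1)`` means
    column i of p against a gap, ``(-1, j)`` a gap against column j of q.
    """
    s = column_scores(p, q, subs)
    n, m = s.shape
    M, X, Y = _global_fill(s, gap_open, gap_extend)
    path: List[Tuple[int, int]] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    score = [M[n, m], X[n, m], Y[n, m]][state]
    eps = 1e-6
    while i > 0 or j > 0:
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - s[i - 1, j - 1]
            state = int(np.argmax([p_ if abs(p_ - target) < eps else _NEG for p_ in prev]))
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((i - 1, -1))
            if abs(X[i, j] - (M[i - 1, j] + gap_open)) < eps:
                state = 0
            i -= 1
        else:
            path.append((-1, j - 1))
            if abs(Y[i, j] - (M[i, j - 1] + gap_open)) < eps:
                state = 0
            j -= 1
    path.reverse()
    return float(score), path


def local_profile_score(
    p: np.ndarray,
    q: np.ndarray,
    subs: np.ndarray = BLOSUM62,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> float:
    """Best local (Smith-Waterman) profile-profile alignment score (>= 0)."""
    s = column_scores(p, q, subs)
    n, m = s.shape
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    cols = np.arange(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = np.maximum(0.0, s[i - 1] + best_prev[:-1])
        X[i, 1:] = np.maximum(M[i - 1, 1:] + gap_open, X[i - 1, 1:] + gap_extend)
        a = M[i] + gap_open - gap_extend * cols
        c = np.maximum.accumulate(a)
        Y[i, 1:] = gap_extend * (cols[1:] - 1) + c[:-1]
        row_best = M[i].max()
        if row_best > best:
            best = float(row_best)
    return best


def apply_path(rows_a: Sequence[str], rows_b: Sequence[str], path) -> Tuple[List[str], List[str]]:
    """Expand two row sets along a global alignment path into merged rows."""
    gap_a = []
    gap_b = []
    for i, j in path:
        gap_a.append(i)
        gap_b.append(j)
    out_a = []
    for row in rows_a:
        out_a.append("".join(row[i] if i >= 0 else "-" for i in gap_a))
    out_b = []
    for row in rows_b:
        out_b.append("".join(row[j] if j >= 0 else "-" for j in gap_b))
    return out_a, out_b
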