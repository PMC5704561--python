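"""Greedy identity/coverage clustering, progressive alignment, column filtering.

Clustering follows the BLASTCLUST model: an edge joins two sequences when
their global-alignment identity and mutual coverage pass the thresholds, and
clusters are the connected components (single linkage) of that graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import _align
from .errors import EmptyProfileError, InvalidArgumentError
from .sequence_io import SequenceRecord

GAP = "-"


@dataclass(frozen=True)
class ClusterParams:
    """Identity and coverage thresholds, both fractions in [0, 1]."""

    identity_threshold: float = 0.5
    coverage_threshold: float = 0.8

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_threshold"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise InvalidArgumentError(f"{name} must be in [0, 1], got {value}")


@dataclass
class Alignment:
    """Gapped rows of equal length plus a kept/removed column mask."""

    rows: List[SequenceRecord]
    column_mask: np.ndarray = None
    gap_fraction: Optional[np.ndarray] = None
    homogeneity: Optional[np.ndarray] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise InvalidArgumentError("alignment needs at least one row")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise InvalidArgumentError("alignment rows have unequal lengths")
        if self.column_mask is None:
            self.column_mask = np.ones(self.length, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if self.column_mask.shape != (self.length,):
                raise InvalidArgumentError("column mask length mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def kind(self) -> str:
        return self.rows[0].kind

    def row_strings(self) -> List[str]:
        return [r.residues for r in self.rows]

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.column_mask)


@dataclass
class Cluster:
    id: str
    members: List[SequenceRecord]
    alignment: Optional[Alignment] = None

    @property
    def size(self) -> int:
        return len(self.members)

    def member_ids(self) -> List[str]:
        return [m.id for m in self.members]


@dataclass
class ClusterSet:
    clusters: List[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> List[int]:
        return [c.size for c in self.clusters]


def _is_nucleotide(kind: str) -> bool:
    return kind in ("cds", "rrna")


def _make_aligner(kind: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if _is_nucleotide(kind):
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    return aligner


def identity_from_gapped(sa: str, sb: str) -> Tuple[float, float, float]:
    """Identity/coverage from one pair of gapped aligned strings.

    Identity is matches over aligned columns excluding terminal-gap columns;
    internal gaps count as mismatches. Coverage of x is the number of its
    residues inside the non-terminal region over its full length.
    """
    nongap_a = [i for i, c in enumerate(sa) if c != GAP]
    nongap_b = [i for i, c in enumerate(sb) if c != GAP]
    start = max(nongap_a[0], nongap_b[0])
    end = min(nongap_a[-1], nongap_b[-1])
    if end < start:
        return 0.0, 0.0, 0.0
    span = range(start, end + 1)
    matches = sum(1 for i in span if sa[i] == sb[i] and sa[i] != GAP)
    ncols = end - start + 1
    len_a = len(sa) - sa.count(GAP)
    len_b = len(sb) - sb.count(GAP)
    cov_a = sum(1 for i in span if sa[i] != GAP) / len_a
    cov_b = sum(1 for i in span if sb[i] != GAP) / len_b
    return matches / ncols, cov_a, cov_b


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> Tuple[float, float, float]:
    """Global-alignment identity and per-sequence coverages for a pair.

    Identity is computed over non-terminal-gap columns (internal gaps count
    as mismatches); coverage of x is the fraction of x inside that span.
    """
    if not a.residues or not b.residues:
        raise InvalidArgumentError("empty sequence")
    if _is_nucleotide(a.kind) != _is_nucleotide(b.kind):
        raise InvalidArgumentError("sequences are from different alphabets")
    aligner = _make_aligner(a.kind)
    aln = aligner.align(a.residues, b.residues)[0]
    return identity_from_gapped(str(aln[0]), str(aln[1]))


def greedy_cluster(seqs: Sequence[SequenceRecord], params: ClusterParams) -> ClusterSet:
    """Single-linkage clusters of the identity/coverage threshold graph.

    Deterministic and invariant to input order: sequences are sorted by id,
    clusters ordered by size (descending) then smallest member id.
    """
    if not seqs:
        raise InvalidArgumentError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda s: s.id)
    ids = [s.id for s in ordered]
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate sequence ids")
    parent = list(range(len(ordered)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if find(i) == find(j):
                continue
            ident, cov_a, cov_b = pairwise_identity(ordered[i], ordered[j])
            if ident >= params.identity_threshold and min(cov_a, cov_b) >= params.coverage_threshold:
                parent[find(j)] = find(i)

    groups: Dict[int, List[SequenceRecord]] = {}
    for i, seq in enumerate(ordered):
        groups.setdefault(find(i), []).append(seq)
    members_sorted = sorted(groups.values(), key=lambda g: (-len(g), g[0].id))
    clusters = [
        Cluster(id=f"C{k + 1:04d}", members=group) for k, group in enumerate(members_sorted)
    ]
    return ClusterSet(clusters)


def _alphabet_for(kind: str):
    if _is_nucleotide(kind):
        return _align.NT_INDEX, _align.NUC_MATRIX, -5.0, -2.0
    return _align.AA_INDEX, _align.BLOSUM62, _align.GAP_OPEN, _align.GAP_EXTEND


def progressive_align(seqs: Sequence[SequenceRecord]) -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Guide distances are 1 - pairwise identity; group merges use global
    profile-profile alignment with sum-of-pairs expected BLOSUM62 scores.
    """
    if not seqs:
        raise InvalidArgumentError("no sequences to align")
    if len(seqs) == 1:
        return Alignment(rows=list(seqs))
    alpha, subs, gap_open, gap_extend = _alphabet_for(seqs[0].kind)
    n = len(seqs)
    if n == 2:
        order = [0, 1]
        merges = [(0, 1)]
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ident, _, _ = pairwise_identity(seqs[i], seqs[j])
                dist[i, j] = dist[j, i] = 1.0 - ident
        linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in linkage]
        order = None
    groups: Dict[int, List[int]] = {i: [i] for i in range(n)}
    rows: Dict[int, List[str]] = {i: [seqs[i].residues] for i in range(n)}
    score = None
    next_id = n
    for a, b in merges:
        pa = _align.column_frequencies(rows[a], alpha)
        pb = _align.column_frequencies(rows[b], alpha)
        score, path = _align.global_profile_align(pa, pb, subs, gap_open, gap_extend)
        new_a, new_b = _align.apply_path(rows[a], rows[b], path)
        rows[next_id] = new_a + new_b
        groups[next_id] = groups.pop(a) + groups.pop(b)
        del rows[a], rows[b]
        next_id += 1
    final = next_id - 1
    by_index = dict(zip(groups[final], rows[final]))
    out_rows = [replace(seqs[i], residues=by_index[i]) for i in range(n)]
    for i, seq in enumerate(seqs):
        assert out_rows[i].residues.replace(GAP, "") == seq.residues, "ungap invariant"
    return Alignment(rows=out_rows, score=score)


def filter_columns(
    aln: Alignment, max_gap_fraction: float = 0.5, min_homogeneity: float = 0.1
) -> Alignment:
    """Mask columns with too many gaps or too little residue homogeneity.

    A column is removed iff gap_fraction > max_gap_fraction or homogeneity <
    min_homogeneity. Homogeneity is the fraction of identical unordered
    residue pairs among the column's non-gap residues (1.0 with fewer than
    two residues). Recomputed from the raw columns, hence idempotent.
    """
    if aln.length == 0:
        raise InvalidArgumentError("alignment has zero columns")
    n_rows = aln.n_rows
    gap_fraction = np.zeros(aln.length)
    homogeneity = np.zeros(aln.length)
    strings = aln.row_strings()
    for col in range(aln.length):
        residues = [row[col] for row in strings if row[col] != GAP]
        gap_fraction[col] = (n_rows - len(residues)) / n_rows
        k = len(residues)
        if k < 2:
            homogeneity[col] = 1.0
        else:
            counts: Dict[str, int] = {}
            for res in residues:
                counts[res] = counts.get(res, 0) + 1
            same = sum(c * (c - 1) // 2 for c in counts.values())
            homogeneity[col] = same / (k * (k - 1) // 2)
    mask = ~((gap_fraction > max_gap_fraction) | (homogeneity < min_homogeneity))
    return Alignment(
        rows=list(aln.rows),
        column_mask=mask,
        gap_fraction=gap_fraction,
        homogeneity=homogeneity,
        score=aln.score,
    )


@dataclass
class Profile:
    """Residue frequencies on the kept, non-empty columns of an alignment."""

    freqs: np.ndarray  # (n_columns, alphabet size)
    n_sequences: int
    column_indices: np.ndarray
    kind: str = "protein"

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


def build_profile(aln: Alignment, pseudocount: float = 1.0 / 20.0) -> Profile:
    """Frequency profile over kept columns with an add-1/20 pseudocount.

    freq(a) = (count(a) + 1/20) / (n_nongap + 1); gaps are excluded from the
    denominator. All-gap columns are dropped from the profile.
    """
    kept = aln.kept_indices()
    if kept.size == 0:
        raise EmptyProfileError("all columns are masked")
    alpha, _, _, _ = _alphabet_for(aln.kind)
    k = len(alpha)
    strings = aln.row_strings()
    freq_rows = []
    indices = []
    for col in kept:
        counts = np.zeros(k)
        n_nongap = 0
        for row in strings:
            idx = alpha.get(row[col])
            if idx is not None:
                counts[idx] += 1
                n_nongap += 1
        if n_nongap == 0:
            continue
        freq_rows.append((counts + pseudocount) / (n_nongap + k * pseudocount))
        indices.append(col)
    if not freq_rows:
        raise EmptyProfileError("no non-empty kept columns")
    return Profile(
        freqs=np.array(freq_rows),
        n_sequences=aln.n_rows,
        column_indices=np.array(indices),
        kind=aln.kind,
    )
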