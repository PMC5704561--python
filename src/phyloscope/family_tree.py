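"""Family-level tree construction for diverse sequence sets.

The procedure: score clusters against each other with a local profile-profile
aligner, iteratively merge highly similar clusters (pairwise score to
self-score ratio above a threshold), build per-cluster neighbor-joining trees
with bootstrap supports, build a UPGMA dendrogram over the remaining cluster
dissimilarities, midpoint-root the cluster trees and graft them onto the
dendrogram tips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _align
from .cluster_align import (
    Alignment,
    Cluster,
    ClusterSet,
    Profile,
    build_profile,
    filter_columns,
    progressive_align,
    _alphabet_for,
)
from .errors import InvalidArgumentError
from .tree import PhyloTree, TreeNode

logger = logging.getLogger(__name__)

#: distance assigned to saturated pairs; matches the coherence sentinel
MAX_DISTANCE = 12.0


# ------------------------------------------------------------- profile score
def profile_score(p: Profile, q: Profile) -> float:
    """Best local profile-profile alignment score (symmetric, >= 0)."""
    if p.length == 0 or q.length == 0:
        raise InvalidArgumentError("empty profile")
    _, subs, gap_open, gap_extend = _alphabet_for(p.kind)
    return _align.local_profile_score(p.freqs, q.freqs, subs, gap_open, gap_extend)


@dataclass
class ClusterSimilarityMatrix:
    """Pairwise profile scores and self-scores over a set of clusters."""

    ids: List[str]
    scores: np.ndarray
    self_scores: np.ndarray

    def ratio(self, i: int, j: int) -> float:
        denom = min(self.self_scores[i], self.self_scores[j])
        if denom <= 0:
            return 0.0
        return float(self.scores[i, j] / denom)

    def ratio_matrix(self) -> np.ndarray:
        n = len(self.ids)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                out[i, j] = 1.0 if i == j else self.ratio(i, j)
        return out


@dataclass(frozen=True)
class MergeEvent:
    step: int
    cluster_i: str
    cluster_j: str
    ratio: float


def _cluster_profile(cluster: Cluster) -> Profile:
    if cluster.alignment is None:
        cluster.alignment = progressive_align(cluster.members)
    return build_profile(cluster.alignment)


def iterative_merge(
    clusters: ClusterSet,
    ratio_threshold: float = 0.1,
) -> Tuple[ClusterSet, ClusterSimilarityMatrix, List[MergeEvent]]:
    """Merge clusters whose score/self-score ratio exceeds the threshold.

    Highest-ratio pair first, with rescoring after every merge, until no pair
    passes: at most n-1 merges, so termination is guaranteed. Merging aligns
    the two cluster alignments with the global profile-profile aligner.

    Profiles are scored on the alignments' current column masks; callers
    should pass unfiltered alignments (filtering hollows out low-homogeneity
    clusters and biases the self-score normalization) and apply the column
    filter afterwards for tree building.
    """
    if not clusters.clusters:
        raise InvalidArgumentError("no clusters")
    work = [Cluster(c.id, list(c.members), c.alignment) for c in clusters.clusters]
    profiles = [_cluster_profile(c) for c in work]
    n0 = len(work)
    selfs = [profile_score(p, p) for p in profiles]
    score: Dict[Tuple[int, int], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            score[(i, j)] = profile_score(profiles[i], profiles[j])
    active = list(range(n0))
    log: List[MergeEvent] = []
    step = 0
    while True:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                denom = min(selfs[i], selfs[j])
                pair = (min(i, j), max(i, j))
                r = score[pair] / denom if denom > 0 else 0.0
                key = (-r, work[i].id, work[j].id)
                if r > ratio_threshold and (best is None or key < best[0]):
                    best = (key, i, j, r)
        if best is None:
            break
        _, i, j, r = best
        step += 1
        log.append(MergeEvent(step, work[i].id, work[j].id, r))
        merged = _merge_clusters(work[i], work[j])
        work.append(merged)
        profiles.append(build_profile(merged.alignment))
        selfs.append(profile_score(profiles[-1], profiles[-1]))
        new_idx = len(work) - 1
        active = [k for k in active if k not in (i, j)]
        for k in active:
            a, b = min(k, new_idx), max(k, new_idx)
            score[(a, b)] = profile_score(profiles[k], profiles[new_idx])
        active.append(new_idx)
        active.sort(key=lambda k: work[k].id)
    ids = [work[k].id for k in active]
    n = len(active)
    mat = np.zeros((n, n))
    self_arr = np.array([selfs[k] for k in active])
    for a in range(n):
        for b in range(a + 1, n):
            i, j = min(active[a], active[b]), max(active[a], active[b])
            mat[a, b] = mat[b, a] = score[(i, j)]
        mat[a, a] = self_arr[a]
    final = ClusterSet([work[k] for k in active])
    return final, ClusterSimilarityMatrix(ids, mat, self_arr), log


def _merge_clusters(a: Cluster, b: Cluster) -> Cluster:
    alpha, subs, gap_open, gap_extend = _alphabet_for(a.alignment.kind)
    rows_a = a.alignment.row_strings()
    rows_b = b.alignment.row_strings()
    pa = _align.column_frequencies(rows_a, alpha)
    pb = _align.column_frequencies(rows_b, alpha)
    _, path = _align.global_profile_align(pa, pb, subs, gap_open, gap_extend)
    new_a, new_b = _align.apply_path(rows_a, rows_b, path)
    rows = [
        replace(rec, residues=s)
        for rec, s in zip(a.alignment.rows + b.alignment.rows, new_a + new_b)
    ]
    aln = Alignment(rows=rows)
    merged_id = min(a.id, b.id)
    return Cluster(id=merged_id, members=a.members + b.members, alignment=aln)


# --------------------------------------------------------------------- UPGMA
def similarity_to_distance(sim: ClusterSimilarityMatrix) -> np.ndarray:
    """d(i,j) = 1 - score/min(self_i, self_j), floored at zero."""
    n = len(sim.ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = max(0.0, 1.0 - sim.ratio(i, j))
    return dist


def upgma(dist: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Average-linkage (UPGMA) dendrogram; ultrametric, rooted.

    Ties broken by the smallest pair of current cluster indices.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 2:
        raise InvalidArgumentError("need at least two items")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-9):
        raise InvalidArgumentError("distance matrix must be symmetric")
    nodes: Dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                key = (d[frozenset((i, j))], i, j)
                if best is None or key < best:
                    best = key
        dij, i, j = best
        height = dij / 2.0
        parent = TreeNode()
        for child_idx in (i, j):
            child = nodes[child_idx]
            child.length = height - heights[child_idx]
            parent.add_child(child)
        nodes[nxt] = parent
        heights[nxt] = height
        sizes[nxt] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            d[frozenset((nxt, k))] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return PhyloTree(nodes[active[0]], rooted=True)


# ------------------------------------------------------------------------ NJ
def _encode_rows(aln: Alignment) -> np.ndarray:
    alpha, _, _, _ = _alphabet_for(aln.kind)
    kept = aln.kept_indices()
    out = np.full((aln.n_rows, kept.size), -1, dtype=np.int8)
    for r, row in enumerate(aln.row_strings()):
        for c, col in enumerate(kept):
            out[r, c] = alpha.get(row[col], -1)
    return out


def _p_distances(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            total = int(valid.sum())
            if total == 0:
                p[i, j] = p[j, i] = 1.0
            else:
                diff = int((codes[i][valid] != codes[j][valid]).sum())
                p[i, j] = p[j, i] = diff / total
    return p


def correct_distances(p: np.ndarray, model: str, cap: float = MAX_DISTANCE) -> np.ndarray:
    """Divergence correction: scoredist-style for protein, Jukes-Cantor for
    nucleotide; saturated pairs are capped."""
    if model == "protein":
        arg = 1.0 - p - 0.2 * p ** 2
    elif model == "nucleotide":
        arg = 1.0 - 4.0 * p / 3.0
    else:
        raise InvalidArgumentError(f"unknown model {model!r}")
    ok = arg > 0
    raw = np.where(ok, -np.log(np.where(ok, arg, 1.0)), cap)
    if model == "nucleotide":
        raw = np.where(ok, 0.75 * raw, cap)
    d = np.minimum(raw, cap)
    saturated = int((~ok).sum() // 2)
    if saturated:
        logger.info("capped %d saturated pairs at %g", saturated, cap)
    np.fill_diagonal(d, 0.0)
    return d


def nj_from_distances(dist: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Classic neighbor joining; exact on additive matrices; unrooted
    (trifurcating root). Negative branch-length estimates are clamped to 0."""
    n = len(labels)
    if n < 3:
        raise InvalidArgumentError("neighbor joining needs at least 3 taxa")
    d = {frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    nodes: Dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[frozenset((i, k))] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[frozenset((i, j))] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d[frozenset((i, j))]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[nxt] = parent
        for k in active:
            if k in (i, j):
                continue
            d[frozenset((nxt, k))] = 0.5 * (
                d[frozenset((i, k))] + d[frozenset((j, k))] - dij
            )
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    i, j, k = active
    dij, dik, djk = d[frozenset((i, j))], d[frozenset((i, k))], d[frozenset((j, k))]
    root = TreeNode()
    for idx, length in ((i, (dij + dik - djk) / 2), (j, (dij + djk - dik) / 2),
                        (k, (dik + djk - dij) / 2)):
        nodes[idx].length = max(length, 0.0)
        root.add_child(nodes[idx])
    return PhyloTree(root, rooted=False)


def nj_tree(
    aln: Alignment,
    model: Optional[str] = None,
    bootstrap: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Neighbor-joining tree from corrected p-distances, with bootstrap
    supports (bipartition frequencies, in percent) on internal nodes."""
    if aln.n_rows < 3:
        raise InvalidArgumentError("need at least 3 sequences")
    if model is None:
        model = "nucleotide" if aln.kind in ("cds", "rrna") else "protein"
    codes = _encode_rows(aln)
    if codes.shape[1] == 0:
        raise InvalidArgumentError("no kept columns")
    labels = [r.id for r in aln.rows]
    dist = correct_distances(_p_distances(codes), model)
    tree = nj_from_distances(dist, labels)
    tree.leaf_genome = {r.id: r.genome_id for r in aln.rows}
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: Dict[frozenset, int] = {}
        ncols = codes.shape[1]
        for _ in range(bootstrap):
            cols = rng.integers(0, ncols, size=ncols)
            bdist = correct_distances(_p_distances(codes[:, cols]), model)
            for part in nj_from_distances(bdist, labels).bipartitions():
                counts[part] = counts.get(part, 0) + 1
        all_leaves = frozenset(labels)
        clade: Dict[int, frozenset] = {}
        for node in tree.postorder():
            if node.is_leaf:
                clade[id(node)] = frozenset([node.name])
            else:
                clade[id(node)] = frozenset().union(*(clade[id(c)] for c in node.children))
        for node in tree.preorder():
            if node.is_leaf or node is tree.root:
                continue
            side = clade[id(node)]
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            part = min(side, other, key=lambda s: (len(s), sorted(s)))
            node.support = 100.0 * counts.get(part, 0) / bootstrap
    return tree


# ------------------------------------------------------------ midpoint root
def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties are broken by the lexicographically smallest leaf pair. The input is
    not modified.
    """
    tree = tree.copy()
    leaves = tree.leaves()
    if len(leaves) < 2:
        tree.rooted = True
        return tree
    names, mat = tree.patristic_matrix()
    best = None
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            key = (-mat[i, j], names[i], names[j])
            if best is None or key < best:
                best = key
    diameter, name_a, name_b = -best[0], best[1], best[2]
    leaf_a, leaf_b = tree.find(name_a), tree.find(name_b)
    # node path a -> lca -> b
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent
    anc_b_set = set()
    node = leaf_b
    while node is not None:
        anc_b_set.add(id(node))
        node = node.parent
    lca = next(n for n in anc_a if id(n) in anc_b_set)
    path_a = anc_a[: anc_a.index(lca) + 1]  # a ... lca
    path_b = []
    node = leaf_b
    while node is not lca:
        path_b.append(node)
        node = node.parent
    path_b.append(lca)
    # full node path from a to b
    path = path_a + list(reversed(path_b))[1:]
    half = diameter / 2.0
    walked = 0.0
    for u, v in zip(path, path[1:]):
        child = u if u.parent is v else v
        length = child.length or 0.0
        if walked + length >= half - 1e-12:
            # midpoint lies on this edge, at (half - walked) from u
            if u is child:
                dist_from_child = half - walked
            else:
                dist_from_child = length - (half - walked)
            dist_from_child = min(max(dist_from_child, 0.0), length)
            tree.reroot_on_edge(child, dist_from_child)
            tree.rooted = True
            return tree
        walked += length
    raise AssertionError("midpoint not found on path")  # pragma: no cover


# ---------------------------------------------------------------- grafting
def graft(dendrogram: PhyloTree, subtrees: Dict[str, PhyloTree]) -> PhyloTree:
    """Replace every dendrogram tip with its (rooted) cluster subtree."""
    tips = set(dendrogram.leaf_names())
    if tips != set(subtrees):
        missing = tips ^ set(subtrees)
        raise InvalidArgumentError(f"dendrogram tips and subtree keys differ: {missing}")
    out = dendrogram.copy()
    leaf_genome: Dict[str, str] = {}
    for tip in list(out.leaves()):
        sub = subtrees[tip.name].copy()
        out.replace_leaf(tip, sub.root)
        leaf_genome.update(sub.leaf_genome)
    out.leaf_genome = leaf_genome
    out.rooted = True
    return out
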