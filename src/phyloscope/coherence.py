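"""Gene-tree / species-tree coherence statistic.

Builds a per-genome-pair table of protein-tree and rRNA-tree patristic
distances and reports their Spearman rank correlation. Pairs whose members
fall in clusters that were never aligned together receive fixed sentinel
distances (12 for proteins, 3 for rRNA); when a genome pair has several
cross-genome member pairs, the shortest distance (after sentinel
substitution) represents the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedCorrelationError
from .tree import PhyloTree

PROTEIN_SENTINEL = 12.0
RRNA_SENTINEL = 3.0

PAIR_COLUMNS = [
    "genome_a",
    "genome_b",
    "protein_distance",
    "rrna_distance",
    "protein_sentinel",
    "rrna_sentinel",
]


def patristic_distances(tree: PhyloTree) -> pd.DataFrame:
    """Leaf-by-leaf matrix of branch-length path distances."""
    names, mat = tree.patristic_matrix()
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass
class _Side:
    """Per-genome member distances for one marker (protein or rRNA)."""

    by_genome: Dict[str, List[Tuple[int, str]]]  # genome -> [(tree idx, leaf)]
    matrices: List[pd.DataFrame]

    @classmethod
    def build(cls, trees: Sequence[PhyloTree], leaf_genome: Optional[Mapping[str, str]] = None):
        by_genome: Dict[str, List[Tuple[int, str]]] = {}
        matrices = []
        for t_idx, tree in enumerate(trees):
            matrices.append(patristic_distances(tree))
            for leaf in tree.leaf_names():
                genome = (leaf_genome or tree.leaf_genome).get(leaf)
                if genome is None:
                    raise InvalidArgumentError(f"no genome mapping for leaf {leaf!r}")
                by_genome.setdefault(genome, []).append((t_idx, leaf))
        return cls(by_genome, matrices)

    def min_distance(self, genome_a: str, genome_b: str, sentinel: float) -> Tuple[float, bool]:
        """Shortest cross-genome distance; sentinel replaces cross-tree pairs."""
        best = np.inf
        used_sentinel = True
        for t_a, leaf_a in self.by_genome[genome_a]:
            for t_b, leaf_b in self.by_genome[genome_b]:
                if t_a == t_b:
                    dist = float(self.matrices[t_a].loc[leaf_a, leaf_b])
                    in_tree = True
                else:
                    dist = sentinel
                    in_tree = False
                if dist < best or (dist == best and in_tree and used_sentinel):
                    best = dist
                    used_sentinel = not in_tree
        return best, used_sentinel


def assemble_pairs(
    protein_trees: Sequence[PhyloTree],
    rrna_trees: Sequence[PhyloTree],
    protein_leaf_genome: Optional[Mapping[str, str]] = None,
    rrna_leaf_genome: Optional[Mapping[str, str]] = None,
    protein_sentinel: float = PROTEIN_SENTINEL,
    rrna_sentinel: float = RRNA_SENTINEL,
) -> pd.DataFrame:
    """Genome-pair distance table from per-cluster protein and rRNA trees.

    A genome enters only if it has at least one family member; each unordered
    pair of such genomes (that both carry an rRNA) yields one row. Distances
    between members in different trees (unaligned clusters) use the sentinel;
    the minimum is taken after sentinel substitution, so a single in-tree
    pair beats any number of sentinels.
    """
    prot = _Side.build(protein_trees, protein_leaf_genome)
    rrna = _Side.build(rrna_trees, rrna_leaf_genome)
    genomes = sorted(g for g in prot.by_genome if g in rrna.by_genome)
    rows = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            d_prot, prot_flag = prot.min_distance(ga, gb, protein_sentinel)
            d_rrna, rrna_flag = rrna.min_distance(ga, gb, rrna_sentinel)
            rows.append([ga, gb, d_prot, d_rrna, prot_flag, rrna_flag])
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank Spearman; the exact 1 - 6*sum(d^2)/(n(n^2-1)) formula is
    used in the tie-free case, Pearson on ranks otherwise."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    n = len(x)
    if len(np.unique(x)) == n and len(np.unique(y)) == n:
        d2 = float(((rx - ry) ** 2).sum())
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(stats.spearmanr(x, y).statistic)


def rank_correlation(table: pd.DataFrame) -> float:
    """Spearman rho between protein and rRNA distances (average ranks on
    ties)."""
    if len(table) < 3:
        raise InvalidArgumentError("need at least 3 genome pairs")
    x = table["protein_distance"].to_numpy(dtype=float)
    y = table["rrna_distance"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one distance column")
    return _spearman(x, y)


def colocated_gene_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Spearman rho between two genes' protein distances over the same
    genome-pair set (for co-located gene pairs)."""
    key = ["genome_a", "genome_b"]
    a = table_a.sort_values(key).reset_index(drop=True)
    b = table_b.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not (a[key].values == b[key].values).all():
        raise InvalidArgumentError("tables cover different genome-pair sets")
    if len(a) < 3:
        raise InvalidArgumentError("need at least 3 genome pairs")
    x = a["protein_distance"].to_numpy(dtype=float)
    y = b["protein_distance"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one distance column")
    return _spearman(x, y)


def write_pair_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
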