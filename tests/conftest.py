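from __future__ import annotations

import numpy as np
import pytest

from phyloscope.sequence_io import SequenceRecord
from phyloscope.tree import PhyloTree, TreeNode

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, length))


def random_nucleotide(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, length))


def mutate(rng: np.random.Generator, seq: str, p: float, alphabet: str = AA) -> str:
    out = []
    k = len(alphabet)
    for c in seq:
        if rng.random() < p:
            out.append(alphabet[int(rng.integers(0, k))])
        else:
            out.append(c)
    return "".join(out)


def random_tree(rng: np.random.Generator, names: list[str]) -> PhyloTree:
    """Random binary tree with exponential branch lengths over given leaves."""
    nodes = [TreeNode(name=n, length=float(rng.exponential(1.0)) + 0.05) for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.exponential(1.0)) + 0.05)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root, rooted=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def protein_family(rng):
    """Ten related proteins (80% identity to a common ancestor)."""
    base = random_protein(rng, 120)
    return [
        SequenceRecord(f"fam{i:02d}", f"G{i:02d}", mutate(rng, base, 0.2))
        for i in range(10)
    ]
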