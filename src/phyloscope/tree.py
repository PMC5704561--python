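"""Rooted/unrooted phylogenetic trees with branch lengths.

A deliberately small tree model: nodes with parent links, branch lengths and
optional support values, plus the surgery primitives the rest of the package
needs (rerooting on an edge, leaf replacement for grafting, patristic
distances). Newick parsing is delegated to dendropy; writing is direct.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterator, List, Optional, Tuple

import numpy as np

from .errors import FormatError, InvalidArgumentError


class TreeNode:
    """A single tree node; ``length`` is the branch to the parent (None at root)."""

    __slots__ = ("name", "length", "support", "rate", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        rate: float = 1.0,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        #: lineage-specific rate multiplier (used by the simulator)
        self.rate = rate
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, len={self.length})"


class PhyloTree:
    """Tree over named leaves with optional leaf→genome mapping."""

    def __init__(
        self,
        root: TreeNode,
        rooted: bool = True,
        leaf_genome: Optional[Dict[str, str]] = None,
    ) -> None:
        self.root = root
        self.rooted = rooted
        self.leaf_genome = dict(leaf_genome) if leaf_genome else {}

    # ------------------------------------------------------------------ walks
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        names = [n.name or "" for n in self.leaves()]
        return names

    def n_leaves(self) -> int:
        return len(self.leaves())

    def find(self, name: str) -> TreeNode:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(name)

    # ------------------------------------------------------------------ copy
    def copy(self) -> "PhyloTree":
        def _copy(node: TreeNode) -> TreeNode:
            dup = TreeNode(node.name, node.length, node.support, node.rate)
            for child in node.children:
                dup.add_child(_copy(child))
            return dup

        return PhyloTree(_copy(self.root), rooted=self.rooted, leaf_genome=self.leaf_genome)

    # ------------------------------------------------------------- distances
    def depths(self) -> Dict[TreeNode, float]:
        """Distance of every node from the root along branch lengths."""
        out: Dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def patristic_matrix(self) -> Tuple[List[str], np.ndarray]:
        """Leaf names (sorted) and the symmetric matrix of path distances."""
        leaves = self.leaves()
        for leaf in leaves:
            if leaf is not self.root and leaf.length is None:
                raise InvalidArgumentError(f"leaf {leaf.name!r} has no branch length")
        leaves.sort(key=lambda n: n.name or "")
        chains: List[Dict[int, float]] = []
        for leaf in leaves:
            chain: Dict[int, float] = {}
            node, dist = leaf, 0.0
            while node is not None:
                chain[id(node)] = dist
                if node.parent is not None:
                    if node.length is None:
                        raise InvalidArgumentError(
                            f"node above {leaf.name!r} has no branch length"
                        )
                    dist += node.length
                node = node.parent
            chains.append(chain)
        # ancestor chains ordered leaf->root; the first shared node is the LCA
        orders = []
        for leaf in leaves:
            order = []
            node = leaf
            while node is not None:
                order.append(id(node))
                node = node.parent
            orders.append(order)
        n = len(leaves)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                cj = chains[j]
                for node_id in orders[i]:
                    if node_id in cj:
                        mat[i, j] = mat[j, i] = chains[i][node_id] + cj[node_id]
                        break
        return [leaf.name or "" for leaf in leaves], mat

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n is not self.root)

    def height(self) -> float:
        depths = self.depths()
        return max(depths[leaf] for leaf in self.leaves())

    def scale(self, factor: float) -> "PhyloTree":
        for node in self.preorder():
            if node.length is not None:
                node.length *= factor
        return self

    # ------------------------------------------------------------- surgery
    def suppress_unifurcations(self) -> None:
        """Splice out internal nodes with a single child, summing lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    # a root above a single leaf is kept (degenerate 1-leaf tree)
                    if not child.is_leaf:
                        child.parent = None
                        child.length = None
                        self.root = child
                        changed = True
                    continue
                parent = node.parent
                idx = parent.children.index(node)
                child.length = (child.length or 0.0) + (node.length or 0.0)
                child.parent = parent
                parent.children[idx] = child
                changed = True

    def reroot_on_edge(self, child: TreeNode, dist_from_child: float) -> "PhyloTree":
        """Place a new root on the edge above ``child`` at ``dist_from_child``."""
        if child.parent is None:
            raise InvalidArgumentError("cannot reroot on the root node")
        edge_len = child.length or 0.0
        if not (0.0 <= dist_from_child <= edge_len + 1e-12):
            raise InvalidArgumentError("rerooting point outside the edge")
        old_parent = child.parent
        old_parent.children.remove(child)
        new_root = TreeNode()
        child.length = dist_from_child
        new_root.add_child(child)
        prev, prev_len = new_root, edge_len - dist_from_child
        node: Optional[TreeNode] = old_parent
        while node is not None:
            parent = node.parent
            node_len = node.length
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            prev.add_child(node)
            node.length = prev_len
            prev_len = node_len
            prev = node
            node = parent
        self.root = new_root
        self.rooted = True
        self.suppress_unifurcations()
        return self

    def replace_leaf(self, leaf: TreeNode, subtree_root: TreeNode) -> None:
        """Substitute ``subtree_root`` for ``leaf``, keeping the leaf's branch."""
        subtree_root.length = leaf.length
        subtree_root.support = leaf.support
        if leaf.parent is None:
            self.root = subtree_root
            subtree_root.parent = None
            subtree_root.length = None
        else:
            parent = leaf.parent
            idx = parent.children.index(leaf)
            parent.children[idx] = subtree_root
            subtree_root.parent = parent

    # --------------------------------------------------------- bipartitions
    def bipartitions(self) -> set:
        """Canonical non-trivial bipartitions as frozensets of leaf names."""
        all_leaves = frozenset(self.leaf_names())
        parts = set()
        clade: Dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                clade[id(node)] = frozenset([node.name])
            else:
                clade[id(node)] = frozenset().union(*(clade[id(c)] for c in node.children))
        for node in self.preorder():
            side = clade[id(node)]
            if node is self.root or len(side) < 2 or len(all_leaves - side) < 2:
                continue
            other = all_leaves - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return parts

    # ------------------------------------------------------------------ I/O
    def to_newick(self) -> str:
        def fmt_len(x: Optional[float]) -> str:
            return "" if x is None else f":{format(x, '.12g')}"

        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name or ''}{fmt_len(node.length)}"
            inner = ",".join(render(c) for c in node.children)
            if node.support is not None:
                label = format(node.support, ".12g")
            else:
                label = node.name or ""
            return f"({inner}){label}{fmt_len(node.length)}"

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"newick parse error: {exc}") from exc

        def convert(dnode) -> TreeNode:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            else:
                name = dnode.label
            node = TreeNode(name=None, length=dnode.edge.length)
            if dnode.is_leaf():
                node.name = name
            elif name is not None:
                try:
                    node.support = float(name)
                except ValueError:
                    node.name = name
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
            return node

        root = convert(dtree.seed_node)
        root.length = None
        return cls(root)


def map_leaf_names(tree: PhyloTree, fn: Callable[[str], str]) -> PhyloTree:
    for leaf in tree.leaves():
        leaf.name = fn(leaf.name or "")
    tree.leaf_genome = {fn(k): v for k, v in tree.leaf_genome.items()}
    return tree
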