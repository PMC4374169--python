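"""Small rooted-tree container: newick output, bipartitions, consensus.

Trees here are rooted, possibly multifurcating, with optional per-node
support values (fraction of bootstrap replicates containing the clade) and
linkage heights.  Clades are compared as leaf-label sets, so consensus
construction is a tally of clades over a common leaf set followed by
nesting of the retained (mutually compatible) clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SupportedTree:
    """Rooted tree over named leaves with optional branch supports."""

    root: TreeNode

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(self.root.leaves())

    def clades(self, nontrivial: bool = True) -> set[frozenset]:
        """Leaf-sets of the internal nodes (excluding leaves and, when
        ``nontrivial``, the root clade of all leaves)."""
        out: set[frozenset] = set()
        all_leaves = self.leaf_names

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            s = frozenset().union(*(walk(c) for c in node.children))
            if len(s) > 1 and not (nontrivial and s == all_leaves):
                out.add(s)
            return s

        walk(self.root)
        return out

    def supports(self) -> dict[frozenset, float]:
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            s = frozenset().union(*(walk(c) for c in node.children))
            if node.support is not None:
                out[s] = node.support
            return s

        walk(self.root)
        return out

    def to_newick(self, support_as_label: bool = True) -> str:
        def fmt(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                label = ""
                if support_as_label and node.support is not None:
                    label = f"{node.support:g}"
                elif node.name:
                    label = node.name
                s = f"({inner}){label}"
            if parent_height is not None:
                s += f":{abs(parent_height - node.height):g}"
            return s

        return fmt(self.root, None) + ";"


def tree_from_linkage(Z, labels: list[str]) -> SupportedTree:
    """Build a tree from a SciPy linkage matrix (leaves named by labels)."""
    import numpy as np

    Z = np.asarray(Z)
    n = len(labels)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=labels[i], height=0.0) for i in range(n)
    }
    for k, (a, b, h, _cnt) in enumerate(Z):
        nodes[n + k] = TreeNode(
            children=[nodes[int(a)], nodes[int(b)]], height=float(h)
        )
    return SupportedTree(root=nodes[n + len(Z) - 1])


def consensus_tree(trees: list[SupportedTree], threshold: float = 0.8) -> SupportedTree:
    """Consensus of rooted trees on one leaf set, keeping clades whose
    frequency strictly exceeds ``threshold``.

    ``threshold`` must lie in [0.5, 1): above one half, all retained clades
    are mutually compatible, so they nest into a unique (possibly
    multifurcating) tree.  Retained clades carry their frequency as the
    support value.
    """
    if not trees:
        raise ValueError("no trees given")
    if not (0.5 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0.5, 1)")
    leaves = trees[0].leaf_names
    for t in trees[1:]:
        if t.leaf_names != leaves:
            raise ValueError("trees have inconsistent leaf sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for c in t.clades():
            counts[c] = counts.get(c, 0) + 1
    n = len(trees)
    kept = {c: cnt / n for c, cnt in counts.items() if cnt / n > threshold}
    # nest retained clades: process by decreasing size, attach under the
    # smallest already-placed clade containing them
    root = TreeNode(height=1.0)
    placed: list[tuple[frozenset, TreeNode]] = [(leaves, root)]
    for clade in sorted(kept, key=lambda c: (-len(c), sorted(c))):
        node = TreeNode(support=kept[clade], height=0.5)
        parent = min(
            (p for p in placed if clade <= p[0]), key=lambda p: len(p[0])
        )
        parent[1].children.append(node)
        placed.append((clade, node))
    # attach each leaf under its smallest containing clade
    for leaf in sorted(leaves):
        parent = min(
            (p for p in placed if leaf in p[0]), key=lambda p: len(p[0])
        )
        parent[1].children.append(TreeNode(name=leaf, height=0.0))
    return SupportedTree(root=root)
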