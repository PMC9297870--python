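"""Minimal unrooted-tree structure with branch lengths and node supports."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    """Node of a (possibly multifurcating) tree.

    ``length`` is the branch length of the edge above the node;
    ``support`` (percentage, 0-100) annotates the edge above internal
    nodes and is None when unset.
    """

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    # ------------------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name or "" for lf in self.leaves()]

    def postorder(self) -> list["TreeNode"]:
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.postorder())
        out.append(self)
        return out

    # ------------------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted bipartitions induced by internal edges.

        Each bipartition is canonicalized as the smaller leaf-name side
        (ties broken by sorted order) so that topologically identical
        trees produce identical sets regardless of rooting.
        """
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue  # trivial split
            parts.add(_canonical(side, other))
        return parts

    def find_clade(self, names: frozenset[str]) -> "TreeNode | None":
        """Internal node whose leaf set equals ``names`` (or its complement)."""
        all_leaves = frozenset(self.leaf_names())
        for node in self.postorder():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if side == names or all_leaves - side == names:
                return node
        return None


def _canonical(a: frozenset[str], b: frozenset[str]) -> frozenset[str]:
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return min(a, b, key=lambda s: sorted(s))
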