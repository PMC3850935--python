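"""Light rooted-tree container used by the simulator and likelihood engine.

Newick parsing is delegated to dendropy; this module only adds the two
things dendropy trees do not carry conveniently for codon-model work:
a stable postorder node indexing and per-edge foreground flags for
branch-site models (the ``#1`` label convention).
"""

from __future__ import annotations

import re
from typing import Iterator, Optional

import dendropy

_FG_SENTINEL = "__FGMARK__"


class TreeNode:
    __slots__ = ("children", "length", "label", "foreground", "parent")

    def __init__(self, label: Optional[str] = None, length: float = 0.0,
                 foreground: bool = False):
        self.children: list[TreeNode] = []
        self.length = length
        self.label = label
        self.foreground = foreground
        self.parent: Optional[TreeNode] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree with branch lengths and optional foreground edges."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    # -- foreground handling ----------------------------------------------

    def set_foreground(self, labels) -> int:
        """Mark edges above the named nodes as foreground; returns count."""
        labels = set(labels)
        n = 0
        for node in self.postorder():
            node.foreground = node.label in labels
            n += node.foreground
        return n

    def foreground_labels(self) -> list[str]:
        return [n.label for n in self.postorder() if n.foreground and n.label]

    # -- serialization -----------------------------------------------------

    def to_newick(self, mark_foreground: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            mark = "#1" if (mark_foreground and node.foreground) else ""
            if node.is_leaf:
                return f"{node.label}{mark}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = node.label or ""
            if node.parent is None:
                return f"({inner}){lab}{mark}"
            return f"({inner}){lab}{mark}:{node.length:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse newick; ``#1`` suffixes on labels mark foreground edges."""
        marked = re.sub(r"#\s*1", _FG_SENTINEL, newick)
        dt = dendropy.Tree.get(
            data=marked, schema="newick",
            suppress_internal_node_taxa=False, preserve_underscores=True,
        )
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Tree":
        def convert(dnode) -> TreeNode:
            raw = None
            if dnode.taxon is not None:
                raw = dnode.taxon.label
            elif dnode.label:
                raw = dnode.label
            fg = False
            if raw and _FG_SENTINEL in raw:
                raw = raw.replace(_FG_SENTINEL, "")
                fg = True
            node = TreeNode(label=raw or None,
                            length=float(dnode.edge.length or 0.0),
                            foreground=fg)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_dendropy(self) -> "dendropy.Tree":
        return dendropy.Tree.get(data=self.to_newick(mark_foreground=False),
                                 schema="newick", preserve_underscores=True)

    def copy(self) -> "Tree":
        return Tree.from_newick(self.to_newick())
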