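"""Newick genealogy parsing and serialization.

The CSV genealogy dialect carries one rooted Newick tree per recombination
interval together with a scalar tree depth (max root-to-tip path length, in
the same units as node times). Node times are recovered as
``time(v) = depth - dist_from_root(v)``, anchoring the tips of an ultrametric
tree at the present (time 0) and allowing ancient samples on shorter tips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import dendropy

from .model import ValidationError


@dataclass
class TreeNode:
    """One node of a parsed rooted tree: children list + branch length to parent."""

    label: Optional[str] = None
    length: float = 0.0
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a rooted :class:`TreeNode` tree.

    Branch lengths default to 0 when absent; quoted labels and bracketed
    comments are handled per the Newick standard. Raises ValidationError on
    empty input, unbalanced parentheses, or duplicate tip labels.
    """
    if text is None or not text.strip():
        raise ValidationError("empty Newick input")
    if not text.strip().endswith(";"):
        raise ValidationError("Newick string must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"Newick parse error: {exc}") from None

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        length = 0.0 if dnode.edge.length is None else float(dnode.edge.length)
        node = TreeNode(label=label, length=length)
        node.children = [convert(ch) for ch in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0 if dtree.seed_node.edge.length is None else float(
        dtree.seed_node.edge.length
    )
    tips = [n.label for n in root.leaves()]
    if any(lab is None for lab in tips):
        raise ValidationError("Newick tree has an unlabeled tip")
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"duplicate tip labels: {dup}")
    return root


def newick_to_times(
    root: TreeNode, depth: float, tolerance: float = 1e-9
) -> Dict[int, float]:
    """Assign node times from branch lengths and a tree-depth scalar.

    Returns ``{id(node): time}`` with ``time = depth - dist_from_root`` and
    ``dist_from_root(root) = 0``. A computed time below ``-tolerance`` is a
    validation error; small negative round-off is clamped to 0.
    """
    if depth <= 0:
        raise ValidationError(f"tree depth must be positive, got {depth}")
    times: Dict[int, float] = {}

    def visit(node: TreeNode, dist: float) -> None:
        if node.length < 0:
            raise ValidationError(f"negative branch length {node.length}")
        t = depth - dist
        if t < -tolerance:
            raise ValidationError(
                f"node {node.label or '<internal>'} at root distance {dist} "
                f"gives negative time {t}"
            )
        times[id(node)] = max(t, 0.0)
        for ch in node.children:
            visit(ch, dist + ch.length)

    visit(root, 0.0)
    return times


def tree_depth(root: TreeNode) -> float:
    """Max root-to-tip path length."""
    best = 0.0

    def visit(node: TreeNode, dist: float) -> None:
        nonlocal best
        if node.is_leaf:
            best = max(best, dist)
        for ch in node.children:
            visit(ch, dist + ch.length)

    visit(root, 0.0)
    return best


def write_newick(root: TreeNode, precision: int = 17) -> str:
    """Serialize a rooted tree with branch lengths, quoting labels when needed."""
    out = io.StringIO()

    def quote(label: str) -> str:
        if any(c in label for c in "()[]{}/\\,;:=*'\"`<> \t\n"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def visit(node: TreeNode, is_root: bool) -> None:
        if node.children:
            out.write("(")
            for i, ch in enumerate(node.children):
                if i:
                    out.write(",")
                visit(ch, False)
            out.write(")")
        if node.label is not None:
            out.write(quote(node.label))
        if not is_root:
            out.write(f":{node.length:.{precision}g}")
    visit(root, True)
    out.write(";")
    return out.getvalue()
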