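"""On-demand decoding of local genealogies from the edge table.

A succinct tree sequence stores each parent/child edge once with the genomic
span on which it is active. The genealogy at any position p is the forest of
edges whose span contains p; the genealogy changes only at *breakpoints* —
the distinct edge span endpoints. Decoding a window is an incremental sweep:
edges are inserted and removed in genomic order, with all removals at a
breakpoint applied before insertions so a child switching parents never
transiently has two.

Edge orderings (insertion by ``(left, time[parent], parent, child)``,
removal by ``(right, time[parent], parent, child)``) make the sweep — and
hence every downstream payload — deterministic; correctness does not depend
on within-breakpoint order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .model import NONE, GenomicInterval, TreeSequenceData, ValidationError


@dataclass
class LocalTree:
    """One local genealogy on a half-open genomic interval.

    ``parent`` maps every node id to its parent id (NONE for roots and for
    nodes absent from this tree). ``roots`` lists the parentless nodes that
    are present (samples, or ancestors of an active edge); isolated
    non-sample nodes are not roots.
    """

    interval: GenomicInterval
    parent: np.ndarray
    roots: List[int]
    index: int

    @property
    def num_nodes(self) -> int:
        return len(self.parent)

    def children_map(self) -> Dict[int, List[int]]:
        """parent id -> sorted child ids, for nodes present in this tree."""
        out: Dict[int, List[int]] = {}
        for c in np.flatnonzero(self.parent != NONE):
            out.setdefault(int(self.parent[c]), []).append(int(c))
        for v in out:
            out[v].sort()
        return out

    def present_nodes(self) -> np.ndarray:
        """Sorted ids of nodes appearing in this tree (roots, internals, leaves)."""
        present = set(self.roots)
        for c in np.flatnonzero(self.parent != NONE):
            present.add(int(c))
            present.add(int(self.parent[c]))
        return np.array(sorted(present), dtype=np.int64)

    def postorder(self) -> List[int]:
        """Deterministic postorder: children before parents, roots ascending,
        siblings ascending by id."""
        children = self.children_map()
        order: List[int] = []
        for root in sorted(self.roots):
            stack: List[Tuple[int, bool]] = [(root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for ch in reversed(children.get(node, [])):
                        stack.append((ch, False))
        return order

    def leaves(self) -> List[int]:
        children = self.children_map()
        return [v for v in self.postorder() if v not in children]

    def mrca(self, ts: TreeSequenceData, nodes) -> int:
        """Most recent common ancestor of the given node set, or NONE."""
        nodes = list(nodes)
        if not nodes:
            raise ValidationError("mrca of an empty node set")
        paths = []
        for v in nodes:
            path = []
            u = int(v)
            while u != NONE:
                path.append(u)
                u = int(self.parent[u])
            paths.append(path)
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        if not common:
            return NONE
        return min(common, key=lambda v: ts.nodes.time[v])


def breakpoints(ts: TreeSequenceData) -> np.ndarray:
    """Sorted distinct coordinates 0 = b_0 < ... < b_K = L delimiting local trees."""
    pts = {0.0, float(ts.sequence_length)}
    pts.update(float(x) for x in ts.edges.left)
    pts.update(float(x) for x in ts.edges.right)
    return np.array(sorted(pts), dtype=np.float64)


def _edge_orders(ts: TreeSequenceData) -> Tuple[np.ndarray, np.ndarray]:
    e = ts.edges
    tp = ts.nodes.time[e.parent]
    ins = np.lexsort((e.child, e.parent, tp, e.left))
    rem = np.lexsort((e.child, e.parent, tp, e.right))
    return ins, rem


@dataclass
class SweepState:
    """Incremental decoder state: the current tree plus resumable sweep pointers."""

    ts: TreeSequenceData
    bps: np.ndarray
    ins_order: np.ndarray
    rem_order: np.ndarray
    parent: np.ndarray
    tree_index: int
    ins_ptr: int  # edges (in insertion order) applied so far
    rem_ptr: int  # edges (in removal order) applied so far
    # per-breakpoint operations of the most recent step, for diffing
    last_removed: List[int] = field(default_factory=list)
    last_inserted: List[int] = field(default_factory=list)

    @classmethod
    def start(cls, ts: TreeSequenceData, bps: np.ndarray | None = None) -> "SweepState":
        """State positioned on tree 0 (interval [b_0, b_1))."""
        if bps is None:
            bps = breakpoints(ts)
        ins, rem = _edge_orders(ts)
        state = cls(
            ts=ts,
            bps=bps,
            ins_order=ins,
            rem_order=rem,
            parent=np.full(ts.num_nodes, NONE, dtype=np.int64),
            tree_index=-1,
            ins_ptr=0,
            rem_ptr=0,
        )
        state.step_forward()
        return state

    @property
    def num_trees(self) -> int:
        return len(self.bps) - 1

    def interval(self) -> GenomicInterval:
        k = self.tree_index
        return GenomicInterval(float(self.bps[k]), float(self.bps[k + 1]))

    def step_forward(self) -> None:
        if self.tree_index + 1 >= self.num_trees:
            raise ValidationError("cannot advance past the last tree")
        b = self.bps[self.tree_index + 1]
        e = self.ts.edges
        removed, inserted = [], []
        # removals strictly before insertions at a shared breakpoint
        while self.rem_ptr < len(self.rem_order):
            j = self.rem_order[self.rem_ptr]
            if e.right[j] > b:
                break
            self.parent[e.child[j]] = NONE
            removed.append(int(j))
            self.rem_ptr += 1
        while self.ins_ptr < len(self.ins_order):
            j = self.ins_order[self.ins_ptr]
            if e.left[j] > b:
                break
            self.parent[e.child[j]] = e.parent[j]
            inserted.append(int(j))
            self.ins_ptr += 1
        self.tree_index += 1
        self.last_removed, self.last_inserted = removed, inserted

    def step_backward(self) -> None:
        if self.tree_index <= 0:
            raise ValidationError("cannot step back past the first tree")
        b = self.bps[self.tree_index]
        e = self.ts.edges
        # undo insertions at b, then undo removals at b (exact inverse order)
        while self.ins_ptr > 0:
            j = self.ins_order[self.ins_ptr - 1]
            if e.left[j] != b:
                break
            self.parent[e.child[j]] = NONE
            self.ins_ptr -= 1
        while self.rem_ptr > 0:
            j = self.rem_order[self.rem_ptr - 1]
            if e.right[j] != b:
                break
            self.parent[e.child[j]] = e.parent[j]
            self.rem_ptr -= 1
        self.tree_index -= 1
        self.last_removed, self.last_inserted = [], []

    def current_tree(self) -> LocalTree:
        return _materialize(self.ts, self.parent, self.interval(), self.tree_index)


def advance(state: SweepState, direction: int) -> SweepState:
    """Step the sweep to the adjacent tree (+1 forward, -1 backward), in place."""
    if direction == 1:
        state.step_forward()
    elif direction == -1:
        state.step_backward()
    else:
        raise ValidationError(f"direction must be +1 or -1, got {direction}")
    return state


def _materialize(
    ts: TreeSequenceData, parent: np.ndarray, interval: GenomicInterval, index: int
) -> LocalTree:
    parent = parent.copy()
    has_child = np.zeros(ts.num_nodes, dtype=bool)
    linked = parent != NONE
    has_child[parent[linked]] = True
    present = linked | has_child | ts.nodes.is_sample
    roots = sorted(int(v) for v in np.flatnonzero(present & ~linked))
    return LocalTree(interval=interval, parent=parent, roots=roots, index=index)


def sweep(ts: TreeSequenceData) -> Iterator[LocalTree]:
    """Yield every local tree of the sequence in genomic order."""
    state = SweepState.start(ts)
    yield state.current_tree()
    while state.tree_index + 1 < state.num_trees:
        state.step_forward()
        yield state.current_tree()


def extract_window(ts: TreeSequenceData, window: GenomicInterval) -> List[LocalTree]:
    """Local trees whose intervals intersect the window, in genomic order.

    Intervals are reported un-clipped: the first/last tree may extend beyond
    the window so interval markers can be drawn correctly.
    """
    if window.end > ts.sequence_length:
        raise ValidationError(
            f"window [{window.start}, {window.end}) exceeds sequence length "
            f"{ts.sequence_length}"
        )
    out: List[LocalTree] = []
    for tree in sweep(ts):
        if tree.interval.start >= window.end:
            break
        if tree.interval.intersects(window):
            out.append(tree)
    return out


def tree_at(ts: TreeSequenceData, position: float) -> LocalTree:
    """The unique local tree covering a position, built by direct point query.

    Binary search over breakpoints finds the interval; the parent array is
    assembled from the edges whose span contains the position — an
    independent route from the incremental sweep, yielding identical trees.
    """
    if not (0 <= position < ts.sequence_length):
        raise ValidationError(
            f"position {position} outside [0, {ts.sequence_length})"
        )
    bps = breakpoints(ts)
    k = int(np.searchsorted(bps, position, side="right")) - 1
    interval = GenomicInterval(float(bps[k]), float(bps[k + 1]))
    e = ts.edges
    parent = np.full(ts.num_nodes, NONE, dtype=np.int64)
    active = (e.left <= position) & (position < e.right)
    parent[e.child[active]] = e.parent[active]
    return _materialize(ts, parent, interval, k)
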