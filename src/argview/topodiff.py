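"""Comparison of consecutive local genealogies along the genome.

Structural change at a breakpoint is reported two ways: the exact edit
(edges removed/inserted by the sweep, and the child nodes whose parent
changed), and a summary statistic — the rooted Robinson-Foulds distance over
sample-leaf clades. Clades are restricted to sample leaves so trees with
different internal node sets remain comparable; rooted-clade RF (rather than
unrooted bipartition RF) is used because local genealogies are rooted. The
distance is the size of the symmetric difference of the two clade sets
(clades of size >= 2, excluding the full sample set), so it is even and at
most 2(n-2) for n samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Sequence, Set

import numpy as np

from .localtrees import LocalTree, SweepState, breakpoints
from .model import NONE, TreeSequenceData, ValidationError


def sample_clades(tree: LocalTree, ts: TreeSequenceData) -> Set[FrozenSet[int]]:
    """Sample-id clades of the internal nodes: size >= 2, full set excluded."""
    is_sample = ts.nodes.is_sample
    full = frozenset(int(s) for s in ts.samples
                     if tree.parent[s] != NONE or int(s) in tree.roots)
    children = tree.children_map()
    below: dict = {}
    clades: Set[FrozenSet[int]] = set()
    for v in tree.postorder():
        kids = children.get(v, [])
        acc = set()
        if is_sample[v]:
            acc.add(int(v))
        for k in kids:
            acc |= below[k]
        below[v] = acc
        if kids:
            clade = frozenset(acc)
            if len(clade) >= 2 and clade != full:
                clades.add(clade)
    return clades


def rf_distance(tree_a: LocalTree, tree_b: LocalTree, ts: TreeSequenceData) -> int:
    """Rooted Robinson-Foulds distance between two local trees."""
    sa = {int(s) for s in ts.samples if tree_a.parent[s] != NONE or int(s) in tree_a.roots}
    sb = {int(s) for s in ts.samples if tree_b.parent[s] != NONE or int(s) in tree_b.roots}
    if sa != sb:
        raise ValidationError(f"sample sets differ: {sorted(sa ^ sb)}")
    ca = sample_clades(tree_a, ts)
    cb = sample_clades(tree_b, ts)
    return len(ca ^ cb)


@dataclass
class TopologyDiff:
    """Structural change at one internal breakpoint."""

    breakpoint: float
    left_tree_index: int
    edges_removed: List[int]  # edge table row ids
    edges_inserted: List[int]
    changed_nodes: List[int]  # children whose parent differs across the breakpoint
    rf: int


def diff_consecutive(
    trees: Sequence[LocalTree], ts: TreeSequenceData
) -> List[TopologyDiff]:
    """One TopologyDiff per internal breakpoint of a consecutive tree run.

    Edge operations are taken from the sweep's per-breakpoint insertions and
    removals; changed_nodes and rf are computed from the two parent arrays.
    """
    trees = list(trees)
    if not trees:
        return []
    for a, b in zip(trees[:-1], trees[1:]):
        if b.index != a.index + 1 or b.interval.start != a.interval.end:
            raise ValidationError(
                f"trees {a.index} and {b.index} are not genomically consecutive"
            )
    bps = breakpoints(ts)
    state = SweepState.start(ts, bps)
    while state.tree_index < trees[0].index:
        state.step_forward()
    diffs: List[TopologyDiff] = []
    for left, right in zip(trees[:-1], trees[1:]):
        state.step_forward()
        changed = sorted(
            int(c) for c in np.flatnonzero(left.parent != right.parent)
        )
        diffs.append(
            TopologyDiff(
                breakpoint=float(left.interval.end),
                left_tree_index=left.index,
                edges_removed=list(state.last_removed),
                edges_inserted=list(state.last_inserted),
                changed_nodes=changed,
                rf=rf_distance(left, right, ts),
            )
        )
    return diffs


def diff_track_text(
    diffs: Sequence[TopologyDiff],
    trees: Sequence[LocalTree],
    sequence_name: str = "seq",
) -> str:
    """bedGraph text: per local tree, the RF value at its left breakpoint
    (0 for the first tree)."""
    trees = list(trees)
    if not trees:
        raise ValidationError("no trees to write")
    rf_at = {d.left_tree_index + 1: d.rf for d in diffs}
    lines = [
        f"{sequence_name}\t{_fmt(t.interval.start)}\t{_fmt(t.interval.end)}\t"
        f"{rf_at.get(t.index, 0)}"
        for t in trees
    ]
    return "\n".join(lines) + "\n"


def diff_track(
    diffs: Sequence[TopologyDiff],
    trees: Sequence[LocalTree],
    path: str,
    sequence_name: str = "seq",
) -> None:
    """Write the bedGraph RF track to a file."""
    with open(path, "w") as fh:
        fh.write(diff_track_text(diffs, trees, sequence_name))


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.12g}"
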