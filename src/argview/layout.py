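"""Layout of local genealogies in genomic-position x coalescent-time space.

Trees of a window occupy consecutive horizontal *slots* (equal width, or
width proportional to genomic interval length), with tips on a unit grid
inside each slot and internal nodes at the mean of their children's x.
The vertical axis is coalescent time under a choice of strictly increasing
transforms: linear (y = t), log (y = log10(1 + t), for deep-time datasets),
or rank (y = rank of t among the window's distinct node times, which evens
out bursts of recent coalescence). Branches are drawn as right-angle
polylines: a vertical riser from the child up to the parent's height, then a
horizontal run to the parent's x. All canvas coordinates are abstract
([0, 1] horizontally); mapping to pixels belongs to the renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .localtrees import LocalTree
from .model import NONE, GenomicInterval, TreeSequenceData, ValidationError

TIME_SCALES = ("linear", "log", "rank")
SLOT_MODES = ("uniform", "genomic")


@dataclass(frozen=True)
class LayoutConfig:
    time_scale: str = "linear"
    slot_mode: str = "uniform"
    tip_order: str = "fixed_sample_order"  # or "ladderized" or "metadata:<column>"
    tree_gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.time_scale not in TIME_SCALES:
            raise ValidationError(f"time_scale must be one of {TIME_SCALES}")
        if self.slot_mode not in SLOT_MODES:
            raise ValidationError(f"slot_mode must be one of {SLOT_MODES}")
        ok = self.tip_order in ("fixed_sample_order", "ladderized") or (
            self.tip_order.startswith("metadata:") and len(self.tip_order) > 9
        )
        if not ok:
            raise ValidationError(f"unknown tip_order {self.tip_order!r}")
        if not (0 <= self.tree_gap_fraction < 0.5):
            raise ValidationError("tree_gap_fraction must lie in [0, 0.5)")


def time_transform(
    t, scale: str = "linear", window_times: Optional[Sequence[float]] = None
):
    """Map coalescent time to canvas y; strictly increasing for every scale.

    ``window_times`` (the distinct node times of the current window) is
    required for the rank scale and ignored otherwise.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValidationError("negative time")
    if scale == "linear":
        y = t
    elif scale == "log":
        y = np.log10(1.0 + t)
    elif scale == "rank":
        if window_times is None:
            raise ValidationError("rank scale needs the window's node times")
        distinct = np.unique(np.asarray(window_times, dtype=np.float64))
        y = np.searchsorted(distinct, t).astype(np.float64)
    else:
        raise ValidationError(f"unknown time scale {scale!r}")
    return float(y) if y.ndim == 0 else y


@dataclass
class BranchSegment:
    """Right-angle polyline for the branch above one node."""

    node: int
    points: List[Tuple[float, float]]


@dataclass
class AxisMap:
    """Monotone correspondence canvas-x <-> genomic coordinate at slot edges."""

    canvas: np.ndarray
    genomic: np.ndarray


@dataclass
class LayoutFrame:
    """Drawable geometry for one local tree."""

    tree_index: int
    interval: GenomicInterval
    node_x: Dict[int, float]
    node_y: Dict[int, float]
    segments: List[BranchSegment]
    tip_order: List[int]
    x_domain: Tuple[float, float]
    y_domain: Tuple[float, float]
    node_time: Dict[int, float] = field(default_factory=dict)
    node_parent: Dict[int, int] = field(default_factory=dict)  # NONE for roots

    def postorder(self) -> List[int]:
        """Deterministic postorder over the frame's nodes (children before
        parents, roots and siblings ascending by id)."""
        children: Dict[int, List[int]] = {}
        roots = []
        for v, p in self.node_parent.items():
            if p == NONE:
                roots.append(v)
            else:
                children.setdefault(p, []).append(v)
        order: List[int] = []
        for root in sorted(roots):
            stack: List[Tuple[int, bool]] = [(root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for ch in sorted(children.get(node, []), reverse=True):
                        stack.append((ch, False))
        return order


def _ordered_tips(tree: LocalTree, ts: TreeSequenceData, config: LayoutConfig) -> List[int]:
    children = tree.children_map()
    tips = [v for v in tree.present_nodes() if int(v) not in children]
    tips = [int(v) for v in tips]
    if config.tip_order == "fixed_sample_order":
        return sorted(tips)
    if config.tip_order == "ladderized":
        sizes: Dict[int, int] = {}
        mintip: Dict[int, int] = {}
        for v in tree.postorder():
            kids = children.get(v, [])
            if not kids:
                sizes[v], mintip[v] = 1, v
            else:
                sizes[v] = sum(sizes[k] for k in kids)
                mintip[v] = min(mintip[k] for k in kids)
        order: List[int] = []
        for root in sorted(tree.roots):
            stack = [root]
            while stack:
                v = stack.pop()
                kids = sorted(children.get(v, []), key=lambda k: (sizes[k], mintip[k]))
                if not kids:
                    order.append(v)
                else:
                    stack.extend(reversed(kids))
        return order
    column = config.tip_order.split(":", 1)[1]
    if ts.metadata is None or column not in ts.metadata.columns:
        raise ValidationError(f"metadata column {column!r} not available for tip ordering")
    meta = ts.metadata[column]

    def key(v: int):
        return (str(meta.get(v, "")), v)

    return sorted(tips, key=key)


def layout_tree(
    tree: LocalTree,
    ts: TreeSequenceData,
    config: LayoutConfig = LayoutConfig(),
    slot: Tuple[float, float] = (0.0, 1.0),
    window_times: Optional[Sequence[float]] = None,
) -> LayoutFrame:
    """Place one local tree: tips on a unit grid in the configured order
    (normalized into ``slot``), internal x at the mean of children, y from
    the time transform."""
    tips = _ordered_tips(tree, ts, config)
    n = len(tips)
    unit = {v: (i / (n - 1) if n > 1 else 0.5) for i, v in enumerate(tips)}
    left, right = slot
    width = right - left
    children = tree.children_map()
    node_x: Dict[int, float] = {}
    node_y: Dict[int, float] = {}
    node_time: Dict[int, float] = {}
    if window_times is None:
        present = tree.present_nodes()
        window_times = ts.nodes.time[present]
    for v in tree.postorder():
        kids = children.get(v, [])
        if kids:
            ux = float(np.mean([node_x[k] for k in kids]))
        else:
            ux = left + unit[v] * width
        node_x[v] = ux
        t = float(ts.nodes.time[v])
        node_time[v] = t
        node_y[v] = float(time_transform(t, config.time_scale, window_times))
    segments: List[BranchSegment] = []
    for v in tree.postorder():
        p = int(tree.parent[v])
        if p == NONE:
            continue
        segments.append(
            BranchSegment(
                node=v,
                points=[
                    (node_x[v], node_y[v]),
                    (node_x[v], node_y[p]),
                    (node_x[p], node_y[p]),
                ],
            )
        )
    y_max = max(node_y.values()) if node_y else 0.0
    node_parent = {v: int(tree.parent[v]) for v in node_x}
    return LayoutFrame(
        tree_index=tree.index,
        interval=tree.interval,
        node_x=node_x,
        node_y=node_y,
        segments=segments,
        tip_order=tips,
        x_domain=(left, right),
        y_domain=(0.0, y_max),
        node_time=node_time,
        node_parent=node_parent,
    )


def layout_window(
    trees: Sequence[LocalTree],
    ts: TreeSequenceData,
    config: LayoutConfig = LayoutConfig(),
) -> Tuple[List[LayoutFrame], AxisMap]:
    """Lay out an ordered window of trees into consecutive slots on [0, 1].

    Returns the frames (sharing one y domain spanning the window) and the
    axis map pairing each slot boundary with its genomic breakpoint.
    """
    if not trees:
        raise ValidationError("empty tree list")
    if config.slot_mode == "uniform":
        widths = np.full(len(trees), 1.0 / len(trees))
    else:
        lengths = np.array([t.interval.length for t in trees], dtype=np.float64)
        widths = lengths / lengths.sum()
    bounds = np.concatenate([[0.0], np.cumsum(widths)])
    bounds[-1] = 1.0
    genomic = np.array(
        [trees[0].interval.start] + [t.interval.end for t in trees], dtype=np.float64
    )
    # shared time context across the window (needed for the rank scale and
    # for a shared y domain)
    all_times: List[float] = []
    for t in trees:
        all_times.extend(float(ts.nodes.time[v]) for v in t.present_nodes())
    frames: List[LayoutFrame] = []
    g = config.tree_gap_fraction
    for i, tree in enumerate(trees):
        pad = g * widths[i] / 2.0
        slot = (float(bounds[i] + pad), float(bounds[i + 1] - pad))
        frames.append(layout_tree(tree, ts, config, slot=slot, window_times=all_times))
    y_max = max(f.y_domain[1] for f in frames)
    for f in frames:
        f.y_domain = (0.0, y_max)
    return frames, AxisMap(canvas=bounds, genomic=genomic)
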