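"""Metadata-driven coloring/search/subsetting, mutation placement, and
genome-browser track overlay.

"Filtering" in the UI sense is a render-state flag (dim the non-matching
samples); "subsetting" is structural — :func:`subset_simplify` restricts a
genealogy to the chosen samples, removing unary pass-through ancestors while
preserving original node ids and times (so pairwise TMRCAs are unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .layout import LayoutFrame
from .localtrees import LocalTree
from .model import NONE, GenomicInterval, TreeSequenceData, ValidationError

# fixed 12-color qualitative cycle (colorblind-aware), embedded so outputs
# are reproducible byte-for-byte
PALETTE_12 = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728",
    "#9467bd", "#8c564b", "#e377c2", "#7f7f7f",
    "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


@dataclass
class CategoryPalette:
    """Deterministic label -> color assignment for one categorical column."""

    column: str
    labels: List[str]  # sorted lexicographically
    color_index: List[int]  # position mod len(PALETTE_12)

    def hex_color(self, label: str) -> str:
        return PALETTE_12[self.color_index[self.labels.index(label)]]

    def code_for_sample(self, metadata: pd.DataFrame, sample_id: int) -> int:
        """Color index for a sample, -1 when the sample has no value."""
        if sample_id not in metadata.index:
            return -1
        val = metadata.loc[sample_id, self.column]
        if pd.isna(val):
            return -1
        return self.color_index[self.labels.index(str(val))]


def assign_colors(metadata: pd.DataFrame, column: str) -> CategoryPalette:
    """Build the palette for a categorical metadata column.

    Labels are sorted lexicographically and assigned color indices cyclically
    (position mod 12); numeric columns are rejected — continuous color ramps
    are out of scope.
    """
    if column not in metadata.columns:
        raise ValidationError(f"unknown metadata column {column!r}")
    series = metadata[column]
    if pd.api.types.is_numeric_dtype(series):
        raise ValidationError(
            f"column {column!r} is numeric; coloring needs a categorical column"
        )
    labels = sorted({str(v) for v in series.dropna()})
    return CategoryPalette(
        column=column,
        labels=labels,
        color_index=[i % len(PALETTE_12) for i in range(len(labels))],
    )


def search_samples(
    metadata: pd.DataFrame, column: str, query: str, mode: str = "exact"
) -> List[int]:
    """Sample ids whose value matches the query; sorted ascending.

    ``exact`` is case-sensitive equality; ``substring`` is case-insensitive
    containment. No match is an empty list, not an error.
    """
    if column not in metadata.columns:
        raise ValidationError(f"unknown metadata column {column!r}")
    if mode not in ("exact", "substring"):
        raise ValidationError(f"mode must be 'exact' or 'substring', got {mode!r}")
    series = metadata[column].dropna().astype(str)
    if mode == "exact":
        hits = series[series == query]
    else:
        hits = series[series.str.contains(query, case=False, regex=False)]
    return sorted(int(i) for i in hits.index)


def subset_simplify(tree: LocalTree, ts: TreeSequenceData, samples) -> LocalTree:
    """The genealogy induced by a sample subset.

    Keeps the nodes on paths from the chosen samples up to their MRCA,
    splices out unary pass-through ancestors, and preserves original ids and
    times. The result's root is the MRCA of the subset.
    """
    chosen = sorted({int(s) for s in samples})
    if not chosen:
        raise ValidationError("empty sample set")
    for s in chosen:
        if not (0 <= s < ts.num_nodes) or not ts.nodes.is_sample[s]:
            raise ValidationError(f"node {s} is not a sample")
        if s not in set(int(v) for v in tree.present_nodes()):
            raise ValidationError(f"sample {s} is not present in tree {tree.index}")
    mrca = tree.mrca(ts, chosen)
    if mrca == NONE:
        raise ValidationError("chosen samples share no common ancestor in this tree")
    # count, per ancestor at or below the MRCA, how many chosen lineages pass through
    n_through: Dict[int, int] = {}
    for s in chosen:
        v = s
        while True:
            n_through[v] = n_through.get(v, 0) + 1
            if v == mrca:
                break
            v = int(tree.parent[v])
    keep: Set[int] = set(chosen) | {mrca}
    keep |= {v for v, k in n_through.items() if k >= 2}
    parent = np.full(tree.num_nodes, NONE, dtype=np.int64)
    for s in chosen:
        v = s
        while v != mrca:
            u = int(tree.parent[v])
            while u not in keep:
                u = int(tree.parent[u])
            if v in keep:
                parent[v] = u
            v = u
    return LocalTree(interval=tree.interval, parent=parent, roots=[mrca], index=tree.index)


@dataclass
class MutationMark:
    """A mutation glyph anchored on the branch above its node in one frame."""

    mutation_id: int
    tree_index: int
    node: int
    position: float
    derived_state: str
    x: float
    y: float
    above_root: bool = False


def place_mutations(ts: TreeSequenceData, frame: LayoutFrame) -> List[MutationMark]:
    """Marks for every mutation whose site lies in the frame's interval.

    Mutations on a branch are spread evenly along it (fraction (i+1)/(k+1)
    from the child, so a lone mutation sits at the midpoint), ordered by site
    position. A mutation above a root is anchored at the root and flagged.
    """
    lo, hi = frame.interval.start, frame.interval.end
    by_node: Dict[int, List[Tuple[float, int]]] = {}
    for m in range(len(ts.mutations)):
        site = int(ts.mutations.site_id[m])
        pos = float(ts.sites.position[site])
        node = int(ts.mutations.node_id[m])
        if not (lo <= pos < hi) or node not in frame.node_x:
            continue
        by_node.setdefault(node, []).append((pos, m))
    marks: List[MutationMark] = []
    for node in sorted(by_node):
        muts = sorted(by_node[node])
        k = len(muts)
        x = frame.node_x[node]
        y0 = frame.node_y[node]
        # parent lookup through the frame's segments: riser tops at parent y
        parent_y = None
        for seg in frame.segments:
            if seg.node == node:
                parent_y = seg.points[1][1]
                break
        for i, (pos, m) in enumerate(muts):
            if parent_y is None:  # root: no branch above
                marks.append(
                    MutationMark(m, frame.tree_index, node, pos,
                                 ts.mutations.derived_state[m], x, y0, above_root=True)
                )
            else:
                frac = (i + 1) / (k + 1)
                marks.append(
                    MutationMark(m, frame.tree_index, node, pos,
                                 ts.mutations.derived_state[m], x,
                                 y0 + frac * (parent_y - y0))
                )
    marks.sort(key=lambda mk: mk.mutation_id)
    return marks


@dataclass
class TrackFeature:
    """One annotation feature with the local trees its interval touches."""

    interval: GenomicInterval
    name: str
    covered_trees: List[int]


def load_bed_track(path: str, ts: TreeSequenceData) -> List[TrackFeature]:
    """Read a BED3+ track (0-based half-open; chromosome column ignored —
    single-sequence model) and intersect features with the tree partition."""
    from .localtrees import breakpoints

    bps = breakpoints(ts)
    L = ts.sequence_length
    features: List[TrackFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"BED line {lineno}: fewer than 3 columns")
            try:
                start, end = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValidationError(f"BED line {lineno}: {exc}") from None
            if end <= start:
                raise ValidationError(f"BED line {lineno}: end {end} <= start {start}")
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            if start >= L or end <= 0:
                warnings.warn(
                    f"BED line {lineno}: feature [{start}, {end}) outside "
                    f"[0, {L}); dropped"
                )
                continue
            clipped = GenomicInterval(max(start, 0.0), min(end, L))
            lo = int(np.searchsorted(bps, clipped.start, side="right")) - 1
            hi = int(np.searchsorted(bps, clipped.end, side="left"))
            covered = list(range(max(lo, 0), min(hi, len(bps) - 1)))
            features.append(TrackFeature(interval=clipped, name=name, covered_trees=covered))
    return features
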