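"""Window request handling: decode -> (optional subset) -> layout ->
annotate -> diff -> serialize, as one pipeline shared by the HTTP service,
the CLI, and the SVG exporter."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .annotate import CategoryPalette, MutationMark, assign_colors, place_mutations, subset_simplify
from .layout import AxisMap, LayoutConfig, LayoutFrame, layout_window
from .localtrees import LocalTree, extract_window
from .model import GenomicInterval, TreeSequenceData, ValidationError
from .payload import serialize_window
from .topodiff import TopologyDiff, diff_consecutive


@dataclass(frozen=True)
class WindowRequest:
    """Everything needed to answer one genomic window query."""

    start: float
    end: float
    max_trees: int = 500
    config: LayoutConfig = field(default_factory=LayoutConfig)
    color_column: Optional[str] = None
    sample_subset: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValidationError(f"window start {self.start} must be < end {self.end}")
        if self.max_trees < 1:
            raise ValidationError("max_trees must be >= 1")


@dataclass
class WindowResult:
    """Intermediate products of one window query, pre-serialization."""

    trees: List[LocalTree]
    frames: List[LayoutFrame]
    axis: AxisMap
    marks: List[MutationMark]
    palette: Optional[CategoryPalette]
    diffs: List[TopologyDiff]
    truncated: bool


def build_window(ts: TreeSequenceData, request: WindowRequest) -> WindowResult:
    trees = extract_window(ts, GenomicInterval(request.start, request.end))
    if not trees:
        raise ValidationError("window covers no local trees")
    truncated = len(trees) > request.max_trees
    trees = trees[: request.max_trees]
    # diffs and rf are computed on the full genealogies; the subset view
    # changes what is drawn, not where the genome's structure changes
    diffs = diff_consecutive(trees, ts) if len(trees) > 1 else []
    shown = trees
    if request.sample_subset:
        shown = [subset_simplify(t, ts, request.sample_subset) for t in trees]
    frames, axis = layout_window(shown, ts, request.config)
    palette = None
    if request.color_column is not None:
        if ts.metadata is None:
            raise ValidationError("dataset has no sample metadata")
        palette = assign_colors(ts.metadata, request.color_column)
    marks: List[MutationMark] = []
    for f in frames:
        marks.extend(place_mutations(ts, f))
    return WindowResult(
        trees=trees,
        frames=frames,
        axis=axis,
        marks=marks,
        palette=palette,
        diffs=diffs,
        truncated=truncated,
    )


def window_payload(ts: TreeSequenceData, request: WindowRequest) -> Tuple[bytes, WindowResult]:
    result = build_window(ts, request)
    data = serialize_window(
        result.frames, result.marks, ts, palette=result.palette, diffs=result.diffs
    )
    return data, result
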