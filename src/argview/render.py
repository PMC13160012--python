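"""Static SVG export of window payloads.

The renderer consumes *only* the columnar payload contract — it deserializes
the byte stream and draws from the decoded batches, which demonstrates that
the payload alone is sufficient for a client renderer. Output is SVG 1.1
with fixed float formatting, so identical payloads give byte-identical
documents (golden-file friendly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

from .annotate import PALETTE_12
from .model import ValidationError
from .payload import DecodedWindow, deserialize_window


@dataclass(frozen=True)
class RenderSpec:
    width: int = 800
    height: int = 500
    margin: int = 40
    stroke_width: float = 1.0
    font_size: int = 10
    show_mutations: bool = True
    highlight_diff: bool = False  # thicken trees whose rf_left > 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.margin < 0:
            raise ValidationError("render dimensions must be positive")
        if 2 * self.margin >= min(self.width, self.height):
            raise ValidationError("margins leave no drawing area")


def _f(x: float) -> str:
    return f"{x:.2f}"


def export_svg(
    payload: Union[bytes, DecodedWindow],
    spec: RenderSpec = RenderSpec(),
    path: Optional[str] = None,
) -> str:
    """Render a window payload to an SVG document; optionally write it."""
    decoded = deserialize_window(payload) if isinstance(payload, (bytes, bytearray)) else payload
    frames = decoded.to_frames()
    if not frames:
        raise ValidationError("empty window: nothing to render")
    marks = decoded.to_marks()
    rf_by_tree = dict(zip(decoded.trees["tree_index"], decoded.trees["rf_left"]))

    m = spec.margin
    iw = spec.width - 2 * m
    ih = spec.height - 2 * m
    y_max = max(f.y_domain[1] for f in frames) or 1.0

    def px(x: float) -> float:
        return m + x * iw

    def py(y: float) -> float:  # time grows upward
        return spec.height - m - (y / y_max) * ih

    out: List[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{spec.width}" height="{spec.height}" '
        f'viewBox="0 0 {spec.width} {spec.height}">'
    )
    out.append(f'<rect width="{spec.width}" height="{spec.height}" fill="white"/>')

    # genome axis with breakpoint ticks (slot edges from the trees batch)
    axis_y = spec.height - m + 12
    base_y = spec.height - m
    out.append(
        f'<line class="axis" x1="{_f(px(0))}" y1="{_f(base_y + 4)}" '
        f'x2="{_f(px(1))}" y2="{_f(base_y + 4)}" stroke="black" stroke-width="1"/>'
    )
    ticks = [(frames[0].x_domain[0], frames[0].interval.start)]
    for left, right in zip(frames[:-1], frames[1:]):
        ticks.append(((left.x_domain[1] + right.x_domain[0]) / 2, left.interval.end))
    ticks.append((frames[-1].x_domain[1], frames[-1].interval.end))
    for cx, gpos in ticks:
        out.append(
            f'<line class="tick" x1="{_f(px(cx))}" y1="{_f(base_y + 1)}" '
            f'x2="{_f(px(cx))}" y2="{_f(base_y + 7)}" stroke="black" stroke-width="1"/>'
        )
        out.append(
            f'<text class="ticklabel" x="{_f(px(cx))}" y="{_f(axis_y + 8)}" '
            f'font-size="{spec.font_size}" text-anchor="middle">{gpos:g}</text>'
        )

    # time axis: baseline and maximum, labeled in time units
    t_maxes = [max(f.node_time.values()) for f in frames if f.node_time]
    t_max = max(t_maxes) if t_maxes else 0.0
    out.append(
        f'<line class="axis" x1="{_f(m - 4)}" y1="{_f(py(0))}" '
        f'x2="{_f(m - 4)}" y2="{_f(py(y_max))}" stroke="black" stroke-width="1"/>'
    )
    for yv, label in ((0.0, "0"), (y_max, f"{t_max:g}")):
        out.append(
            f'<text class="timelabel" x="{_f(m - 8)}" y="{_f(py(yv) + 3)}" '
            f'font-size="{spec.font_size}" text-anchor="end">{label}</text>'
        )

    # branches
    color_of = {}
    for _, row in decoded.nodes.iterrows():
        code = int(row["color_code"])
        color_of[(int(row["tree_index"]), int(row["node_id"]))] = (
            PALETTE_12[code % len(PALETTE_12)] if code >= 0 else "#444444"
        )
    for frame in frames:
        sw = spec.stroke_width
        if spec.highlight_diff and rf_by_tree.get(frame.tree_index, 0) > 0:
            sw = spec.stroke_width * 2.5
        for seg in sorted(frame.segments, key=lambda s: s.node):
            pts = " ".join(f"{_f(px(x))},{_f(py(y))}" for x, y in seg.points)
            out.append(
                f'<polyline class="branch" points="{pts}" fill="none" '
                f'stroke="#333333" stroke-width="{sw:g}"/>'
            )
        for v in frame.tip_order:
            out.append(
                f'<circle class="tip" cx="{_f(px(frame.node_x[v]))}" '
                f'cy="{_f(py(frame.node_y[v]))}" r="2.5" '
                f'fill="{color_of.get((frame.tree_index, v), "#444444")}"/>'
            )

    if spec.show_mutations:
        for mk in marks:
            x, y = px(mk.x), py(mk.y)
            out.append(
                f'<g class="mutation"><line x1="{_f(x - 3)}" y1="{_f(y)}" '
                f'x2="{_f(x + 3)}" y2="{_f(y)}" stroke="#d62728" stroke-width="1.5"/>'
                f'<line x1="{_f(x)}" y1="{_f(y - 3)}" x2="{_f(x)}" y2="{_f(y + 3)}" '
                f'stroke="#d62728" stroke-width="1.5"/></g>'
            )

    out.append("</svg>")
    doc = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(doc)
    return doc
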