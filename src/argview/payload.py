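"""Columnar window payloads for streaming to a renderer.

A window's laid-out trees are encoded as three Arrow IPC record batches in
one byte stream:

* ``trees`` — one row per local tree: genomic interval, tree depth, and the
  Robinson-Foulds distance to the previous tree (``rf_left``, 0 for the
  window's first tree);
* ``nodes`` — one row per drawn node, in postorder within each tree (so a
  renderer can draw children before parents in a single pass), with
  ``parent_slot`` giving the row offset of the parent within the same tree
  (-1 for roots), canvas coordinates as float32, and the exact node time as
  float64 (the per-tree min/max of which are the temporal bounds);
* ``mutations`` — one row per mutation mark with its branch anchor.

Canvas coordinates travel as float32 (GPU-buffer practice); genomic
positions as float64 (exact). The stream is framed with a magic tag and the
schema version is carried in each batch's schema metadata — a version
mismatch is a hard error, never a silent coercion.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pyarrow as pa

from .annotate import CategoryPalette, MutationMark
from .layout import BranchSegment, LayoutFrame
from .model import NONE, GenomicInterval, TreeSequenceData, ValidationError
from .topodiff import TopologyDiff

MAGIC = b"AVW0"
SCHEMA_VERSION = "1"
_META = {b"argview_schema": SCHEMA_VERSION.encode()}

TREES_SCHEMA = pa.schema(
    [
        ("tree_index", pa.int32()),
        ("start", pa.float64()),
        ("end", pa.float64()),
        ("depth", pa.float32()),
        ("rf_left", pa.int32()),
    ],
    metadata=_META,
)
NODES_SCHEMA = pa.schema(
    [
        ("tree_index", pa.int32()),
        ("node_id", pa.int32()),
        ("emit_order", pa.int32()),
        ("parent_slot", pa.int32()),
        ("x", pa.float32()),
        ("y", pa.float32()),
        ("time", pa.float64()),
        ("is_sample", pa.uint8()),
        ("color_code", pa.int16()),
    ],
    metadata=_META,
)
MUTATIONS_SCHEMA = pa.schema(
    [
        ("tree_index", pa.int32()),
        ("node_id", pa.int32()),
        ("position", pa.float64()),
        ("x", pa.float32()),
        ("y", pa.float32()),
        ("derived_state", pa.utf8()),
    ],
    metadata=_META,
)


def _frame_depth(frame: LayoutFrame) -> float:
    """Max root-to-tip time span within the frame."""
    children = set()
    for v, p in frame.node_parent.items():
        if p != NONE:
            children.add(p)
    best = 0.0
    for v, p in frame.node_parent.items():
        if v in children:
            continue  # not a leaf
        u, t_leaf = v, frame.node_time[v]
        while frame.node_parent[u] != NONE:
            u = frame.node_parent[u]
        best = max(best, frame.node_time[u] - t_leaf)
    return best


def serialize_window(
    frames: Sequence[LayoutFrame],
    marks: Sequence[MutationMark],
    ts: TreeSequenceData,
    palette: Optional[CategoryPalette] = None,
    diffs: Sequence[TopologyDiff] = (),
) -> bytes:
    """Encode laid-out frames, mutation marks, and diffs as one byte stream."""
    frame_idx = {f.tree_index for f in frames}
    for mk in marks:
        if mk.tree_index not in frame_idx:
            raise ValidationError(
                f"mutation mark references tree {mk.tree_index} absent from frames"
            )
    rf_at: Dict[int, int] = {d.left_tree_index + 1: d.rf for d in diffs}
    t_rows: Dict[str, list] = {k: [] for k in TREES_SCHEMA.names}
    n_rows: Dict[str, list] = {k: [] for k in NODES_SCHEMA.names}
    m_rows: Dict[str, list] = {k: [] for k in MUTATIONS_SCHEMA.names}
    first = min(frame_idx) if frame_idx else 0
    for f in sorted(frames, key=lambda f: f.tree_index):
        t_rows["tree_index"].append(f.tree_index)
        t_rows["start"].append(f.interval.start)
        t_rows["end"].append(f.interval.end)
        t_rows["depth"].append(_frame_depth(f))
        t_rows["rf_left"].append(0 if f.tree_index == first else rf_at.get(f.tree_index, 0))
        order = f.postorder()
        slot = {v: i for i, v in enumerate(order)}
        for i, v in enumerate(order):
            p = f.node_parent[v]
            n_rows["tree_index"].append(f.tree_index)
            n_rows["node_id"].append(v)
            n_rows["emit_order"].append(i)
            n_rows["parent_slot"].append(-1 if p == NONE else slot[p])
            n_rows["x"].append(f.node_x[v])
            n_rows["y"].append(f.node_y[v])
            n_rows["time"].append(f.node_time[v])
            n_rows["is_sample"].append(int(ts.nodes.is_sample[v]))
            code = -1
            if palette is not None and ts.metadata is not None and ts.nodes.is_sample[v]:
                code = palette.code_for_sample(ts.metadata, v)
            n_rows["color_code"].append(code)
    for mk in sorted(marks, key=lambda m: (m.tree_index, m.mutation_id)):
        m_rows["tree_index"].append(mk.tree_index)
        m_rows["node_id"].append(mk.node)
        m_rows["position"].append(mk.position)
        m_rows["x"].append(mk.x)
        m_rows["y"].append(mk.y)
        m_rows["derived_state"].append(mk.derived_state)

    blocks = []
    for schema, rows in (
        (TREES_SCHEMA, t_rows),
        (NODES_SCHEMA, n_rows),
        (MUTATIONS_SCHEMA, m_rows),
    ):
        batch = pa.record_batch(
            [pa.array(rows[name], type=schema.field(name).type) for name in schema.names],
            schema=schema,
        )
        sink = pa.BufferOutputStream()
        with pa.ipc.new_stream(sink, schema) as writer:
            writer.write_batch(batch)
        blocks.append(sink.getvalue().to_pybytes())
    out = [MAGIC, struct.pack("<I", len(blocks))]
    for b in blocks:
        out.append(struct.pack("<Q", len(b)))
        out.append(b)
    return b"".join(out)


@dataclass
class DecodedWindow:
    """Deserialized payload: the three batches as DataFrames, plus
    reconstruction helpers."""

    trees: pd.DataFrame
    nodes: pd.DataFrame
    mutations: pd.DataFrame

    def to_frames(self) -> List[LayoutFrame]:
        """Rebuild LayoutFrames (geometry, parents, segments) from the batches."""
        frames: List[LayoutFrame] = []
        y_max = float(self.nodes["y"].max()) if len(self.nodes) else 0.0
        for _, trow in self.trees.iterrows():
            ti = int(trow["tree_index"])
            sub = self.nodes[self.nodes["tree_index"] == ti]
            ids = sub["node_id"].to_numpy()
            parent_slot = sub["parent_slot"].to_numpy()
            node_parent = {
                int(v): (NONE if s < 0 else int(ids[s]))
                for v, s in zip(ids, parent_slot)
            }
            node_x = {int(v): float(x) for v, x in zip(ids, sub["x"])}
            node_y = {int(v): float(y) for v, y in zip(ids, sub["y"])}
            node_time = {int(v): float(t) for v, t in zip(ids, sub["time"])}
            segments = [
                BranchSegment(
                    node=v,
                    points=[
                        (node_x[v], node_y[v]),
                        (node_x[v], node_y[p]),
                        (node_x[p], node_y[p]),
                    ],
                )
                for v, p in node_parent.items()
                if p != NONE
            ]
            is_sample = {int(v): bool(s) for v, s in zip(ids, sub["is_sample"])}
            tips = sorted(
                (v for v in node_x if is_sample[v]), key=lambda v: node_x[v]
            )
            xs = list(node_x.values())
            frames.append(
                LayoutFrame(
                    tree_index=ti,
                    interval=GenomicInterval(float(trow["start"]), float(trow["end"])),
                    node_x=node_x,
                    node_y=node_y,
                    segments=segments,
                    tip_order=tips,
                    x_domain=(min(xs), max(xs)) if xs else (0.0, 1.0),
                    y_domain=(0.0, y_max),
                    node_time=node_time,
                    node_parent=node_parent,
                )
            )
        return frames

    def to_marks(self) -> List[MutationMark]:
        root_nodes: Dict[Tuple[int, int], bool] = {}
        for _, row in self.nodes.iterrows():
            root_nodes[(int(row["tree_index"]), int(row["node_id"]))] = (
                int(row["parent_slot"]) < 0
            )
        marks = []
        for i, row in self.mutations.iterrows():
            key = (int(row["tree_index"]), int(row["node_id"]))
            marks.append(
                MutationMark(
                    mutation_id=int(i),
                    tree_index=key[0],
                    node=key[1],
                    position=float(row["position"]),
                    derived_state=str(row["derived_state"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    above_root=root_nodes.get(key, False),
                )
            )
        return marks

    @property
    def rf_left(self) -> np.ndarray:
        return self.trees["rf_left"].to_numpy()


def deserialize_window(data: bytes) -> DecodedWindow:
    """Decode a payload byte stream; hard error on version mismatch or truncation."""
    if len(data) < 8 or data[:4] != MAGIC:
        raise ValidationError("not an argview window payload (bad magic)")
    (count,) = struct.unpack_from("<I", data, 4)
    if count != 3:
        raise ValidationError(f"expected 3 batches, header says {count}")
    offset = 8
    tables = []
    for _ in range(count):
        if offset + 8 > len(data):
            raise ValidationError("truncated payload stream")
        (length,) = struct.unpack_from("<Q", data, offset)
        offset += 8
        block = data[offset : offset + length]
        if len(block) != length:
            raise ValidationError("truncated payload stream")
        offset += length
        with pa.ipc.open_stream(pa.BufferReader(block)) as reader:
            meta = reader.schema.metadata or {}
            version = (meta.get(b"argview_schema") or b"?").decode()
            if version != SCHEMA_VERSION:
                raise ValidationError(
                    f"payload schema version {version!r} != supported {SCHEMA_VERSION!r}"
                )
            tables.append(reader.read_all())
    trees, nodes, mutations = (t.to_pandas() for t in tables)
    return DecodedWindow(trees=trees, nodes=nodes, mutations=mutations)
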