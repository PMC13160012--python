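"""Readers and writers for the two genealogy input families.

Succinct tree-sequence containers (``.trees``, compressed ``.tsz``) are
decoded with tskit and converted to this package's
:class:`~argview.model.TreeSequenceData` table contract; all downstream
computation operates on that contract.

The CSV genealogy dialect encodes one local genealogy per recombination
interval: required header columns ``start,end,newick,depth``
(case-insensitive), comma-separated with RFC 4180 quoting, rows sorted by
``start`` with contiguous non-overlapping intervals tiling [0, L). ``newick``
is a rooted tree with branch lengths over a tip set shared by every row;
``depth`` is the max root-to-tip path length (units of node time), which
anchors branch lengths to absolute node times with ultrametric tips at the
present. Additional columns are user-defined per-interval metadata.
"""

from __future__ import annotations

import csv
import os
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .model import (
    NONE,
    EdgeTable,
    GenomicInterval,
    MutationTable,
    NodeTable,
    SiteTable,
    TreeSequenceData,
    ValidationError,
)
from .newick import TreeNode, newick_to_times, parse_newick, tree_depth, write_newick

_TIME_TOL = 1e-9


def _decode_meta(raw) -> dict:
    if isinstance(raw, dict):
        return raw
    if isinstance(raw, bytes):
        if not raw:
            return {}
        try:
            import json

            return json.loads(raw.decode())
        except Exception:
            return {}
    return {}


def _from_tables(tables) -> TreeSequenceData:
    """Convert a tskit TableCollection into the package's table contract."""
    import tskit

    n = len(tables.nodes)
    time = np.asarray(tables.nodes.time, dtype=np.float64).copy()
    is_sample = (
        np.asarray(tables.nodes.flags, dtype=np.uint32) & tskit.NODE_IS_SAMPLE
    ).astype(bool)
    population = np.asarray(tables.nodes.population, dtype=np.int64).copy()
    labels: List[Optional[str]] = [None] * n
    pop_names: Dict[int, str] = {}
    for i, pop in enumerate(tables.populations):
        meta = _decode_meta(pop.metadata)
        pop_names[i] = str(meta.get("name", i))
    meta_rows: Dict[int, dict] = {}
    for i, node in enumerate(tables.nodes):
        meta = _decode_meta(node.metadata)
        if "name" in meta:
            labels[i] = str(meta["name"])
        if is_sample[i]:
            row = {k: v for k, v in meta.items() if np.isscalar(v) or isinstance(v, str)}
            if population[i] != NONE:
                row.setdefault("population", pop_names.get(int(population[i]), str(population[i])))
            meta_rows[i] = row
    metadata = None
    if any(meta_rows.values()):
        metadata = pd.DataFrame.from_dict(meta_rows, orient="index").sort_index()
    edges = tables.edges
    data = TreeSequenceData(
        sequence_length=float(tables.sequence_length),
        nodes=NodeTable(time=time, is_sample=is_sample, population=population, label=labels),
        edges=EdgeTable(
            left=np.asarray(edges.left, dtype=np.float64).copy(),
            right=np.asarray(edges.right, dtype=np.float64).copy(),
            parent=np.asarray(edges.parent, dtype=np.int64).copy(),
            child=np.asarray(edges.child, dtype=np.int64).copy(),
        ),
        sites=SiteTable.from_rows(
            (s.position, s.ancestral_state) for s in tables.sites
        ),
        mutations=MutationTable.from_rows(
            (m.site, m.node, m.derived_state) for m in tables.mutations
        ),
        metadata=metadata,
    )
    return data.validate()


def from_tskit(tsk) -> TreeSequenceData:
    """Convert a tskit TreeSequence into the package's table contract."""
    return _from_tables(tsk.tables)


def load_tree_sequence(path: str) -> TreeSequenceData:
    """Load a ``.trees`` or ``.tsz`` container into TreeSequenceData."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".tsz"):
        try:
            import tszip
        except ImportError:
            raise ValidationError(
                "reading .tsz requires the optional tszip package "
                "(pip install 'argview[tsz]')"
            ) from None
        tsk = tszip.decompress(path)
    elif path.endswith(".trees"):
        import tskit

        try:
            tsk = tskit.load(path)
        except Exception:
            # the codec refuses invalid tree sequences outright; fall back to
            # raw table decoding so our validator can name the offending row
            try:
                tables = tskit.TableCollection.load(path)
            except Exception as exc:
                raise ValidationError(
                    f"cannot decode tree-sequence container: {exc}"
                ) from None
            return _from_tables(tables)
    else:
        raise ValidationError(f"unrecognized extension (want .trees or .tsz): {path}")
    return from_tskit(tsk)


def load_csv_genealogies(path: str) -> TreeSequenceData:
    """Read the CSV genealogy dialect into a single TreeSequenceData."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError("empty CSV file") from None
        rows = list(reader)
    cols = {name.strip().lower(): i for i, name in enumerate(header)}
    for req in ("start", "end", "newick", "depth"):
        if req not in cols:
            raise ValidationError(f"missing required column '{req}'")
    extra_cols = [h for h in header if h.strip().lower() not in ("start", "end", "newick", "depth")]

    parsed = []
    for r, row in enumerate(rows):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            start = float(row[cols["start"]])
            end = float(row[cols["end"]])
            depth = float(row[cols["depth"]])
        except (ValueError, IndexError) as exc:
            raise ValidationError(f"row {r}: {exc}") from None
        tree = parse_newick(row[cols["newick"]])
        times = newick_to_times(tree, depth)
        extras = {h: row[cols[h.strip().lower()]] for h in extra_cols} if extra_cols else {}
        parsed.append((GenomicInterval(start, end), tree, times, extras, r))
    if not parsed:
        raise ValidationError("CSV contains no genealogy rows")

    # intervals: sorted, contiguous, tiling [0, L)
    if parsed[0][0].start != 0:
        raise ValidationError(
            f"row {parsed[0][4]}: intervals must start at 0 (gap before {parsed[0][0].start})"
        )
    for (a, *_, ra), (b, *_, rb) in zip(parsed[:-1], parsed[1:]):
        if b.start < a.end:
            raise ValidationError(f"rows {ra} and {rb}: overlapping intervals")
        if b.start > a.end:
            raise ValidationError(f"rows {ra} and {rb}: gap between intervals")
    sequence_length = parsed[-1][0].end

    tip_sets = [frozenset(n.label for n in tree.leaves()) for _, tree, *_ in parsed]
    for i, ts_i in enumerate(tip_sets[1:], 1):
        if ts_i != tip_sets[0]:
            raise ValidationError(
                f"rows {parsed[0][4]} and {parsed[i][4]}: tip sets differ "
                f"({sorted(tip_sets[0] ^ ts_i)})"
            )

    sample_labels = sorted(tip_sets[0])
    sample_id = {lab: i for i, lab in enumerate(sample_labels)}
    n_samples = len(sample_labels)
    node_time = [np.nan] * n_samples
    node_label: List[Optional[str]] = list(sample_labels)
    edge_rows = []
    for interval, tree, times, _, r in parsed:
        local_id: Dict[int, int] = {}
        for node in tree.walk():
            t = times[id(node)]
            if node.is_leaf:
                nid = sample_id[node.label]
                if np.isnan(node_time[nid]):
                    node_time[nid] = t
                elif abs(node_time[nid] - t) > 1e-6:
                    raise ValidationError(
                        f"row {r}: tip '{node.label}' time {t} conflicts with "
                        f"earlier value {node_time[nid]}"
                    )
            else:
                nid = len(node_time)
                node_time.append(t)
                node_label.append(None)
            local_id[id(node)] = nid
        for node in tree.walk():
            for ch in node.children:
                edge_rows.append(
                    (interval.start, interval.end, local_id[id(node)], local_id[id(ch)])
                )

    nodes = NodeTable(
        time=np.array(node_time, dtype=np.float64),
        is_sample=np.arange(len(node_time)) < n_samples,
        population=np.full(len(node_time), NONE, dtype=np.int64),
        label=node_label,
    )
    interval_metadata = None
    if extra_cols:
        interval_metadata = pd.DataFrame(
            [
                {"start": iv.start, "end": iv.end, **extras}
                for iv, _, _, extras, _ in parsed
            ]
        )
    data = TreeSequenceData(
        sequence_length=sequence_length,
        nodes=nodes,
        edges=EdgeTable.from_rows(edge_rows),
        interval_metadata=interval_metadata,
    )
    return data.validate()


def write_csv_genealogies(ts: TreeSequenceData, path: str, trees=None) -> None:
    """Write one CSV row per local tree (inverse of :func:`load_csv_genealogies`).

    ``trees`` defaults to every local tree of the sequence; pass the result
    of a window extraction to export a sub-region.
    """
    from .localtrees import sweep

    if trees is None:
        trees = sweep(ts)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start", "end", "newick", "depth"])
        for tree in trees:
            if len(tree.roots) != 1:
                raise ValidationError(
                    f"tree {tree.index} has {len(tree.roots)} roots; the CSV "
                    "dialect requires single-rooted genealogies"
                )
            root = _to_treenode(ts, tree, tree.roots[0])
            writer.writerow(
                [
                    _fmt(tree.interval.start),
                    _fmt(tree.interval.end),
                    write_newick(root),
                    _fmt(tree_depth(root)),
                ]
            )


def _fmt(x: float) -> str:
    # shortest exact round-trip representation; integral values without ".0"
    x = float(x)
    return str(int(x)) if x.is_integer() and abs(x) < 2**53 else repr(x)


def _to_treenode(ts: TreeSequenceData, tree, node_id: int) -> TreeNode:
    children = tree.children_map()

    def build(v: int) -> TreeNode:
        kids = children.get(v, [])
        label = ts.node_label(v) if not kids else None
        node = TreeNode(label=label)
        p = int(tree.parent[v])
        if p != NONE:
            node.length = float(ts.nodes.time[p] - ts.nodes.time[v])
        node.children = [build(c) for c in kids]
        return node

    return build(node_id)


def load_metadata_csv(path: str, ts: TreeSequenceData) -> pd.DataFrame:
    """Read tabular sample metadata keyed (first column) by sample id or label.

    Returns a DataFrame indexed by sample node id; attaches nothing — callers
    assign it to ``ts.metadata`` explicitly.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("metadata CSV needs a key column plus at least one attribute")
    key = df.columns[0]
    label_to_id = {
        ts.node_label(int(s)): int(s) for s in ts.samples
    }
    ids = []
    for v in df[key]:
        sv = str(v)
        if sv in label_to_id:
            ids.append(label_to_id[sv])
        else:
            try:
                i = int(v)
            except (TypeError, ValueError):
                raise ValidationError(f"metadata key '{v}' matches no sample") from None
            if not (0 <= i < ts.num_nodes and ts.nodes.is_sample[i]):
                raise ValidationError(f"metadata key '{v}' is not a sample node id")
            ids.append(i)
    out = df.drop(columns=[key])
    out.index = pd.Index(ids, name="sample_id")
    return out
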