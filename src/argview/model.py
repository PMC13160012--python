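"""Tabular data model for succinct tree sequences.

A tree sequence stores the genealogical history of a set of sampled genomes
as a set of tables: *nodes* (haploid genomes, each with an age in generations
before present), *edges* (parent/child relationships, each valid on a
half-open genomic interval), *sites* and *mutations* (variants placed on
branches), plus per-sample metadata. Edges shared by adjacent local trees are
stored once, which is what makes the encoding succinct.

All coordinates are 0-based, half-open ``[start, end)``, floating point.
Every consumer in this package operates on :class:`TreeSequenceData`, not on
any external codec's objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

NONE = -1  # sentinel for "no parent" / "no population"


class ValidationError(ValueError):
    """A table set violates an invariant; the message names the first offending row."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) in base pairs."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> float:
        return self.end - self.start

    def contains(self, position: float) -> bool:
        return self.start <= position < self.end

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class NodeTable:
    """Per-node arrays: age, sample flag, population, optional label.

    Node ids are dense 0..N-1 row indices. ``time`` is in generations before
    present (larger is older); samples sit at the present unless explicitly
    ancient. ``population`` is ``NONE`` (-1) where unassigned.
    """

    time: np.ndarray
    is_sample: np.ndarray
    population: np.ndarray
    label: list

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def empty(cls) -> "NodeTable":
        return cls(
            time=np.empty(0, dtype=np.float64),
            is_sample=np.empty(0, dtype=bool),
            population=np.empty(0, dtype=np.int64),
            label=[],
        )

    @classmethod
    def from_rows(cls, rows) -> "NodeTable":
        """rows: iterable of (time, is_sample[, population[, label]])."""
        rows = list(rows)
        time = np.array([r[0] for r in rows], dtype=np.float64)
        is_sample = np.array([bool(r[1]) for r in rows], dtype=bool)
        population = np.array(
            [r[2] if len(r) > 2 and r[2] is not None else NONE for r in rows],
            dtype=np.int64,
        )
        label = [r[3] if len(r) > 3 else None for r in rows]
        return cls(time, is_sample, population, label)

    @property
    def samples(self) -> np.ndarray:
        return np.flatnonzero(self.is_sample)


@dataclass
class EdgeTable:
    """Per-edge arrays: genomic span [left, right) and parent -> child link."""

    left: np.ndarray
    right: np.ndarray
    parent: np.ndarray
    child: np.ndarray

    def __len__(self) -> int:
        return len(self.left)

    @classmethod
    def empty(cls) -> "EdgeTable":
        f = np.empty(0, dtype=np.float64)
        i = np.empty(0, dtype=np.int64)
        return cls(f.copy(), f.copy(), i.copy(), i.copy())

    @classmethod
    def from_rows(cls, rows) -> "EdgeTable":
        """rows: iterable of (left, right, parent, child)."""
        rows = list(rows)
        return cls(
            left=np.array([r[0] for r in rows], dtype=np.float64),
            right=np.array([r[1] for r in rows], dtype=np.float64),
            parent=np.array([r[2] for r in rows], dtype=np.int64),
            child=np.array([r[3] for r in rows], dtype=np.int64),
        )


@dataclass
class SiteTable:
    position: np.ndarray
    ancestral_state: list

    def __len__(self) -> int:
        return len(self.position)

    @classmethod
    def empty(cls) -> "SiteTable":
        return cls(np.empty(0, dtype=np.float64), [])

    @classmethod
    def from_rows(cls, rows) -> "SiteTable":
        rows = list(rows)
        return cls(
            position=np.array([r[0] for r in rows], dtype=np.float64),
            ancestral_state=[str(r[1]) for r in rows],
        )


@dataclass
class MutationTable:
    site_id: np.ndarray
    node_id: np.ndarray
    derived_state: list

    def __len__(self) -> int:
        return len(self.site_id)

    @classmethod
    def empty(cls) -> "MutationTable":
        i = np.empty(0, dtype=np.int64)
        return cls(i.copy(), i.copy(), [])

    @classmethod
    def from_rows(cls, rows) -> "MutationTable":
        rows = list(rows)
        return cls(
            site_id=np.array([r[0] for r in rows], dtype=np.int64),
            node_id=np.array([r[1] for r in rows], dtype=np.int64),
            derived_state=[str(r[2]) for r in rows],
        )


@dataclass
class TreeSequenceData:
    """The full table set every decoder and annotator in this package consumes.

    ``metadata`` is a DataFrame indexed by sample node id with one column per
    named attribute (categorical text or numeric). ``interval_metadata`` holds
    user-defined per-interval columns from CSV genealogy inputs (may be None).
    """

    sequence_length: float
    nodes: NodeTable
    edges: EdgeTable
    sites: SiteTable = field(default_factory=SiteTable.empty)
    mutations: MutationTable = field(default_factory=MutationTable.empty)
    metadata: Optional[pd.DataFrame] = None
    interval_metadata: Optional[pd.DataFrame] = None

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_samples(self) -> int:
        return int(self.nodes.is_sample.sum())

    @property
    def samples(self) -> np.ndarray:
        return self.nodes.samples

    def node_label(self, node_id: int) -> str:
        lab = self.nodes.label[node_id]
        return str(node_id) if lab is None else str(lab)

    def validate(self) -> "TreeSequenceData":
        """Check every table invariant; raise ValidationError naming the first bad row."""
        L = self.sequence_length
        if not (L > 0 and np.isfinite(L)):
            raise ValidationError(f"sequence_length must be positive and finite, got {L}")
        n = self.num_nodes
        t = self.nodes.time
        if len(t) and (np.any(~np.isfinite(t)) or np.any(t < 0)):
            bad = int(np.flatnonzero(~np.isfinite(t) | (t < 0))[0])
            raise ValidationError(f"node {bad}: time {t[bad]} is not a finite non-negative real")
        e = self.edges
        if len(e):
            def first_bad(mask, message):
                if np.any(mask):
                    i = int(np.flatnonzero(mask)[0])
                    raise ValidationError(f"edge {i}: " + message.format(i=i))

            first_bad(
                (e.parent < 0) | (e.parent >= n) | (e.child < 0) | (e.child >= n),
                "node id out of range",
            )
            first_bad(~(e.left < e.right), "left must be < right")
            first_bad((e.left < 0) | (e.right > L), f"span outside [0, {L}]")
            bad_time = ~(t[e.parent] > t[e.child])
            if np.any(bad_time):
                i = int(np.flatnonzero(bad_time)[0])
                p, c = int(e.parent[i]), int(e.child[i])
                raise ValidationError(
                    f"edge {i}: parent {p} (time {t[p]}) not strictly older than "
                    f"child {c} (time {t[c]})"
                )
            # per-child spans must not overlap
            order = np.lexsort((e.left, e.child))
            a, b = order[:-1], order[1:]
            overlap = (e.child[a] == e.child[b]) & (e.right[a] > e.left[b])
            if np.any(overlap):
                k = int(np.flatnonzero(overlap)[0])
                raise ValidationError(
                    f"edge {int(b[k])}: overlaps edge {int(a[k])} for "
                    f"child {int(e.child[b[k]])}"
                )
        s = self.sites
        for i in range(len(s)):
            if not (0 <= s.position[i] < L):
                raise ValidationError(f"site {i}: position {s.position[i]} outside [0, {L})")
            if i and not (s.position[i] > s.position[i - 1]):
                raise ValidationError(f"site {i}: positions not strictly increasing")
        m = self.mutations
        for i in range(len(m)):
            if not (0 <= m.site_id[i] < len(s)):
                raise ValidationError(f"mutation {i}: invalid site id {m.site_id[i]}")
            if not (0 <= m.node_id[i] < n):
                raise ValidationError(f"mutation {i}: invalid node id {m.node_id[i]}")
        if self.metadata is not None:
            if self.metadata.columns.duplicated().any():
                raise ValidationError("metadata: duplicate column names")
            ids = np.asarray(self.metadata.index)
            bad = [int(i) for i in ids if not (0 <= i < n and self.nodes.is_sample[i])]
            if bad:
                raise ValidationError(f"metadata: id {bad[0]} is not a sample node")
        return self
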