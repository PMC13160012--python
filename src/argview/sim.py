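"""Synthetic tree-sequence generation for testing and demos.

Two generators are provided. *Independent* mode draws an unlinked random
Kingman coalescent tree (exponential inter-coalescence waiting times with
rate k(k-1)/2 while k lineages remain, in coalescent time units) for each
genomic interval. *Linked* mode starts from one coalescent tree and applies
a single random detach/reattach (SPR-like) move per breakpoint, producing
correlated adjacent topologies the way recombination does, while guaranteeing
valid node times by construction — no full ancestral-recombination machinery
is needed for that.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    NONE,
    EdgeTable,
    MutationTable,
    NodeTable,
    SiteTable,
    TreeSequenceData,
    ValidationError,
)


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 10
    n_intervals: int = 5
    sequence_length: float = 100.0
    mutation_count: int = 0
    mode: str = "independent"  # or "linked"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.n_intervals < 1:
            raise ValidationError("n_intervals must be >= 1")
        if self.sequence_length <= 0:
            raise ValidationError("sequence_length must be positive")
        if self.mutation_count < 0:
            raise ValidationError("mutation_count must be >= 0")
        if self.mode not in ("independent", "linked"):
            raise ValidationError(f"unknown mode {self.mode!r}")


def make_fixture_f1() -> TreeSequenceData:
    """The canonical 3-sample, 2-tree fixture used throughout the test suite.

    Sequence length 10 with a breakpoint at 5: tree 0 has topology ((0,1),2)
    rooted at node 4, tree 1 has ((1,2),0) under the same root. One site at
    position 2.0 (ancestral A) carries a derived G above sample 0.
    """
    nodes = NodeTable.from_rows(
        [
            (0.0, True, 0),
            (0.0, True, 0),
            (0.0, True, 1),
            (1.0, False),
            (2.0, False),
            (1.5, False),
        ]
    )
    edges = EdgeTable.from_rows(
        [
            (0, 5, 3, 0),
            (0, 5, 3, 1),
            (0, 5, 4, 3),
            (0, 5, 4, 2),
            (5, 10, 5, 1),
            (5, 10, 5, 2),
            (5, 10, 4, 5),
            (5, 10, 4, 0),
        ]
    )
    metadata = pd.DataFrame({"population": ["EUR", "EUR", "AFR"]}, index=[0, 1, 2])
    metadata.index.name = "sample_id"
    return TreeSequenceData(
        sequence_length=10.0,
        nodes=nodes,
        edges=edges,
        sites=SiteTable.from_rows([(2.0, "A")]),
        mutations=MutationTable.from_rows([(0, 0, "G")]),
        metadata=metadata,
    ).validate()


def _coalescent_tree(
    rng: np.random.Generator, sample_ids: List[int], times: List[float]
) -> Dict[int, int]:
    """Random Kingman tree over the given samples; appends internal times.

    Returns a parent mapping; internal node ids continue from len(times).
    """
    parent: Dict[int, int] = {}
    active = list(sample_ids)
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        new = len(times)
        times.append(t)
        parent[a] = new
        parent[b] = new
        active = [v for v in active if v not in (a, b)] + [new]
    return parent


def _detach_reattach(
    rng: np.random.Generator,
    parent: Dict[int, Optional[int]],
    times: List[float],
    max_tries: int = 50,
) -> Dict[int, Optional[int]]:
    """One random SPR-like move; mutates ``times`` (fresh internal node id)."""
    for _ in range(max_tries):
        work = dict(parent)
        nonroot = sorted(v for v, p in work.items() if p is not None)
        c = int(nonroot[rng.integers(len(nonroot))])
        p = work[c]
        children: Dict[int, List[int]] = {}
        for v, q in work.items():
            if q is not None:
                children.setdefault(q, []).append(v)
        sibs = [v for v in children[p] if v != c]
        # binary trees: detaching always leaves p unary -> splice it out
        if len(sibs) != 1:
            continue
        d = sibs[0]
        g = work.get(p)
        del work[p]
        work[d] = g  # None when p was the root
        del work[c]
        # candidate branches whose time span can contain the attachment
        children2: Dict[int, List[int]] = {}
        for v, q in work.items():
            if q is not None:
                children2.setdefault(q, []).append(v)
        stack = [c]
        forbidden = {c}
        while stack:
            u = stack.pop()
            for v in children2.get(u, []):
                forbidden.add(v)
                stack.append(v)
        cands: List[Tuple[int, Optional[int]]] = []
        for u, q in sorted(work.items()):
            if q is None or u in forbidden:
                continue
            if times[q] > max(times[c], times[u]):
                cands.append((u, q))
        root = next(v for v, q in sorted(work.items()) if q is None)
        if root not in forbidden:
            cands.append((root, None))  # reattach above the current root
        if not cands:
            continue
        u, q = cands[int(rng.integers(len(cands)))]
        lo = max(times[c], times[u])
        if q is None:
            t_att = lo + rng.exponential(1.0)
        else:
            t_att = rng.uniform(lo, times[q])
            if not (lo < t_att < times[q]):
                continue
        w = len(times)
        times.append(float(t_att))
        work[w] = q
        work[u] = w
        work[c] = w
        return work
    raise ValidationError("no feasible detach/reattach move found")


def _draw_boundaries(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    L, k = config.sequence_length, config.n_intervals
    for _ in range(100):
        inner = np.sort(rng.uniform(0, L, size=k - 1)) if k > 1 else np.empty(0)
        bps = np.concatenate([[0.0], inner, [L]])
        if len(np.unique(bps)) == k + 1:
            return bps
    raise ValidationError("could not draw distinct interval boundaries")


def simulate(config: SimConfig) -> TreeSequenceData:
    """Generate a seeded synthetic tree sequence under the configured mode."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    bps = _draw_boundaries(rng, config)
    times: List[float] = [0.0] * n
    sample_ids = list(range(n))
    edge_rows: List[Tuple[float, float, int, int]] = []

    if config.mode == "independent":
        for k in range(config.n_intervals):
            parent = _coalescent_tree(rng, sample_ids, times)
            for c, p in sorted(parent.items()):
                edge_rows.append((bps[k], bps[k + 1], p, c))
    else:
        parent: Dict[int, Optional[int]] = dict(
            _coalescent_tree(rng, sample_ids, times)
        )
        root = next(v for v in range(len(times)) if v not in parent)
        parent[root] = None
        # keep each parent->child edge open across the intervals where it is
        # unchanged, so shared structure is stored once (succinct encoding)
        open_edges: Dict[int, Tuple[int, float]] = {}  # child -> (parent, left)
        for k in range(config.n_intervals):
            if k > 0:
                parent = _detach_reattach(rng, parent, times)
            b = bps[k]
            for c in sorted(set(open_edges) - set(parent)):
                p, left = open_edges.pop(c)
                edge_rows.append((left, b, p, c))
            for c, p in sorted(parent.items()):
                if p is None:
                    continue
                if c in open_edges and open_edges[c][0] != p:
                    old_p, left = open_edges.pop(c)
                    edge_rows.append((left, b, old_p, c))
                if c not in open_edges:
                    open_edges[c] = (p, b)
        for c in sorted(open_edges):
            p, left = open_edges[c]
            edge_rows.append((left, bps[-1], p, c))

    nodes = NodeTable(
        time=np.array(times, dtype=np.float64),
        is_sample=np.arange(len(times)) < n,
        population=np.full(len(times), NONE, dtype=np.int64),
        label=[None] * len(times),
    )
    data = TreeSequenceData(
        sequence_length=config.sequence_length,
        nodes=nodes,
        edges=EdgeTable.from_rows(edge_rows),
    )
    data.validate()
    if config.mutation_count:
        data = _add_mutations(rng, data, config.mutation_count)
    return data.validate()


def _add_mutations(
    rng: np.random.Generator, ts: TreeSequenceData, count: int
) -> TreeSequenceData:
    from .localtrees import tree_at

    L = ts.sequence_length
    positions: set = set()
    while len(positions) < count:
        positions.add(float(rng.uniform(0, L)))
    site_rows, mut_rows = [], []
    for s, pos in enumerate(sorted(positions)):
        tree = tree_at(ts, pos)
        branches = sorted(int(c) for c in np.flatnonzero(tree.parent != NONE))
        node = branches[int(rng.integers(len(branches)))]
        site_rows.append((pos, "A"))
        mut_rows.append((s, node, "T"))
    ts.sites = SiteTable.from_rows(site_rows)
    ts.mutations = MutationTable.from_rows(mut_rows)
    return ts


def make_metadata(
    ts: TreeSequenceData, n_categories: int, seed: int, column: str = "group"
) -> pd.DataFrame:
    """Assign each sample a uniform random category label P0..P{k-1}, seeded."""
    if n_categories < 1:
        raise ValidationError("n_categories must be >= 1")
    rng = np.random.default_rng(seed)
    samples = ts.samples
    labels = [f"P{rng.integers(n_categories)}" for _ in samples]
    df = pd.DataFrame({column: labels}, index=pd.Index(samples, name="sample_id"))
    return df
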