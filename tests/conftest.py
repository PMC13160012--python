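"""Shared fixtures and independent oracles.

The oracles here are deliberately written from scratch against the table
definitions (plain Python loops, per-sample ancestor walks, tskit as an
external cross-check) so they share no code path with the package's sweep
decoder, RF computation, or layout.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Set

import numpy as np
import pytest

import argview as av


@pytest.fixture
def f1() -> av.TreeSequenceData:
    return av.make_fixture_f1()


def point_oracle_parent(ts: av.TreeSequenceData, position: float) -> np.ndarray:
    """Brute-force genealogy at a point: scan every edge row, no sweep."""
    parent = np.full(ts.num_nodes, av.NONE, dtype=np.int64)
    for i in range(len(ts.edges)):
        if ts.edges.left[i] <= position < ts.edges.right[i]:
            parent[int(ts.edges.child[i])] = int(ts.edges.parent[i])
    return parent


def rf_oracle(tree_a: av.LocalTree, tree_b: av.LocalTree, ts: av.TreeSequenceData) -> int:
    """Independent rooted RF: clades materialized by per-sample ancestor walks."""

    def clades(tree: av.LocalTree) -> Set[FrozenSet[int]]:
        below: Dict[int, set] = {}
        samples = [int(s) for s in ts.samples]
        for s in samples:
            v = int(tree.parent[s])
            while v != av.NONE:
                below.setdefault(v, set()).add(s)
                v = int(tree.parent[v])
        full = frozenset(samples)
        return {
            frozenset(m) for m in below.values() if len(m) >= 2 and frozenset(m) != full
        }

    ca, cb = clades(tree_a), clades(tree_b)
    return len(ca ^ cb)


def to_tskit(ts: av.TreeSequenceData):
    """Re-encode a table set as a tskit TreeSequence (external cross-check)."""
    import tskit

    tables = tskit.TableCollection(sequence_length=ts.sequence_length)
    for i in range(ts.num_nodes):
        tables.nodes.add_row(
            flags=tskit.NODE_IS_SAMPLE if ts.nodes.is_sample[i] else 0,
            time=float(ts.nodes.time[i]),
        )
    for i in range(len(ts.edges)):
        tables.edges.add_row(
            left=float(ts.edges.left[i]),
            right=float(ts.edges.right[i]),
            parent=int(ts.edges.parent[i]),
            child=int(ts.edges.child[i]),
        )
    tables.sort()
    return tables.tree_sequence()


def forest_ok(ts: av.TreeSequenceData, tree: av.LocalTree) -> bool:
    """No node with two parents (by construction of the array), no cycles,
    parent strictly older, every sample reaches a root."""
    time = ts.nodes.time
    n = ts.num_nodes
    for c in range(n):
        p = int(tree.parent[c])
        if p != av.NONE and not (time[p] > time[c]):
            return False
    for s in ts.samples:
        seen = set()
        v = int(s)
        while v != av.NONE:
            if v in seen:
                return False  # cycle
            seen.add(v)
            if int(tree.parent[v]) == av.NONE and v not in tree.roots:
                return False
            v = int(tree.parent[v])
    return True


def random_fixture(seed: int, mode: str = "independent", mutations: int = 0) -> av.TreeSequenceData:
    """Bounded random tree sequence for oracle suites (<=30 samples, <=50 intervals)."""
    rng = np.random.default_rng(seed)
    return av.simulate(
        av.SimConfig(
            n_samples=int(rng.integers(2, 31)),
            n_intervals=int(rng.integers(1, 51)),
            sequence_length=float(rng.uniform(10, 1000)),
            mutation_count=mutations,
            mode=mode,
            seed=seed,
        )
    )


def random_tree_pair(seed: int, n_tips: int = 8):
    """Two independent random rooted coalescent trees on a shared tip set."""
    ts = av.simulate(
        av.SimConfig(
            n_samples=n_tips, n_intervals=2, sequence_length=10.0,
            mode="independent", seed=seed,
        )
    )
    trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
    return trees[0], trees[1], ts
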