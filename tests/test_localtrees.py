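"""Sweep decoder: breakpoints, window extraction, random access, stepping."""

import numpy as np
import pytest

import argview as av
from .conftest import forest_ok, point_oracle_parent, random_fixture, to_tskit

FULL = av.GenomicInterval(0, 10)


class TestBreakpoints:
    def test_f1(self, f1):
        np.testing.assert_array_equal(av.breakpoints(f1), [0, 5, 10])

    def test_single_tree(self):
        ts = av.simulate(av.SimConfig(n_samples=4, n_intervals=1, sequence_length=7.0))
        np.testing.assert_array_equal(av.breakpoints(ts), [0, 7.0])

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_equals_edge_endpoint_set(self, seed):
        ts = random_fixture(seed)
        expected = sorted(
            {0.0, ts.sequence_length}
            | set(map(float, ts.edges.left))
            | set(map(float, ts.edges.right))
        )
        np.testing.assert_allclose(av.breakpoints(ts), expected)


class TestExtractWindow:
    def test_f1_full_parent_arrays(self, f1):
        trees = av.extract_window(f1, FULL)
        assert [t.index for t in trees] == [0, 1]
        np.testing.assert_array_equal(trees[0].parent, [3, 3, 4, 4, -1, -1])
        np.testing.assert_array_equal(trees[1].parent, [4, 5, 5, -1, -1, 4])

    def test_inner_window_unclipped_interval(self, f1):
        trees = av.extract_window(f1, av.GenomicInterval(6, 7))
        assert len(trees) == 1
        assert trees[0].index == 1
        assert trees[0].interval == av.GenomicInterval(5, 10)

    def test_invalid_windows(self, f1):
        with pytest.raises(av.ValidationError):
            av.extract_window(f1, av.GenomicInterval(0, 11))
        with pytest.raises(av.ValidationError):
            av.GenomicInterval(7, 7)

    def test_partition_tiles_genome(self, f1):
        for seed in range(5):
            ts = random_fixture(seed, mode="linked")
            trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
            assert trees[0].interval.start == 0.0
            assert trees[-1].interval.end == ts.sequence_length
            for a, b in zip(trees[:-1], trees[1:]):
                assert a.interval.end == b.interval.start

    def test_window_consistency_across_partitions(self):
        """Concatenating sub-window extractions reproduces the single call."""
        ts = random_fixture(21, mode="independent")
        L = ts.sequence_length
        whole = av.extract_window(ts, av.GenomicInterval(0, L))
        cuts = [0, L / 3, L / 2, L]
        pieces = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            for t in av.extract_window(ts, av.GenomicInterval(lo, hi)):
                if not pieces or pieces[-1].index != t.index:
                    pieces.append(t)
        assert [t.index for t in pieces] == [t.index for t in whole]
        for a, b in zip(pieces, whole):
            np.testing.assert_array_equal(a.parent, b.parent)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["independent", "linked"])
    def test_sweep_matches_point_oracle(self, mode):
        """Every decoded tree equals the brute-force edge filter at the
        interval midpoint, and the forest is always valid."""
        for seed in range(15):
            ts = random_fixture(seed + (0 if mode == "independent" else 1000), mode=mode)
            for tree in av.sweep(ts):
                mid = (tree.interval.start + tree.interval.end) / 2
                np.testing.assert_array_equal(
                    tree.parent, point_oracle_parent(ts, mid),
                    err_msg=f"seed={seed} tree={tree.index}",
                )
                assert forest_ok(ts, tree)

    def test_sweep_matches_tskit(self):
        """External cross-check: parent arrays equal tskit's for the same tables."""
        for seed in (3, 7):
            ts = random_fixture(seed, mode="linked")
            tsk = to_tskit(ts)
            ours = list(av.sweep(ts))
            theirs = list(tsk.trees())
            # tskit merges breakpoints with no edge change; align by position
            for tree in ours:
                mid = (tree.interval.start + tree.interval.end) / 2
                tsk_tree = tsk.at(mid)
                for v in range(ts.num_nodes):
                    assert tree.parent[v] == tsk_tree.parent(v)

    def test_msprime_input(self):
        """Decoder agrees with tskit on a real coalescent-with-recombination
        simulation loaded through the container path."""
        import msprime

        sim = msprime.sim_ancestry(
            samples=10, sequence_length=1e5, recombination_rate=1e-7,
            population_size=1e3, random_seed=42,
        )
        ts = av.from_tskit(sim)
        for tree in av.sweep(ts):
            mid = (tree.interval.start + tree.interval.end) / 2
            tsk_tree = sim.at(mid)
            for v in range(ts.num_nodes):
                assert tree.parent[v] == tsk_tree.parent(v)


class TestTreeAt:
    def test_half_open_convention(self, f1):
        assert av.tree_at(f1, 4.999).index == 0
        assert av.tree_at(f1, 5.0).index == 1

    def test_out_of_range(self, f1):
        with pytest.raises(av.ValidationError):
            av.tree_at(f1, 10.0)
        with pytest.raises(av.ValidationError):
            av.tree_at(f1, -0.1)

    def test_matches_extract_window(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            ts = random_fixture(seed, mode="linked")
            trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
            by_index = {t.index: t for t in trees}
            for p in rng.uniform(0, ts.sequence_length, size=200):
                t = av.tree_at(ts, p)
                assert t.interval.contains(p)
                np.testing.assert_array_equal(t.parent, by_index[t.index].parent)


class TestAdvance:
    def test_f1_forward(self, f1):
        state = av.SweepState.start(f1)
        av.advance(state, +1)
        np.testing.assert_array_equal(state.parent, [4, 5, 5, -1, -1, 4])

    def test_involution(self, f1):
        state = av.SweepState.start(f1)
        before = state.parent.copy()
        av.advance(state, +1)
        av.advance(state, -1)
        np.testing.assert_array_equal(state.parent, before)

    def test_stepping_past_ends(self, f1):
        state = av.SweepState.start(f1)
        with pytest.raises(av.ValidationError):
            av.advance(state, -1)
        av.advance(state, +1)
        with pytest.raises(av.ValidationError):
            av.advance(state, +1)

    def test_full_forward_sweep_equals_extract(self):
        ts = random_fixture(33, mode="linked")
        expected = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
        state = av.SweepState.start(ts)
        got = [state.current_tree()]
        while state.tree_index + 1 < state.num_trees:
            av.advance(state, +1)
            got.append(state.current_tree())
        assert len(got) == len(expected)
        for a, b in zip(got, expected):
            np.testing.assert_array_equal(a.parent, b.parent)

    def test_random_walk_involution(self):
        """A seeded random walk of +1/-1 steps always matches a fresh build."""
        ts = random_fixture(8, mode="linked")
        state = av.SweepState.start(ts)
        rng = np.random.default_rng(0)
        for _ in range(100):
            if state.tree_index == 0:
                step = 1
            elif state.tree_index == state.num_trees - 1:
                step = -1
            else:
                step = int(rng.choice([-1, 1]))
            av.advance(state, step)
            mid = (state.interval().start + state.interval().end) / 2
            np.testing.assert_array_equal(state.parent, point_oracle_parent(ts, mid))
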