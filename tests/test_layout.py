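"""Layout geometry: time transforms, tip placement, slots, determinism."""

import numpy as np
import pytest

import argview as av
from .conftest import random_fixture

FULL = av.GenomicInterval(0, 10)


class TestTimeTransform:
    @pytest.mark.parametrize("scale", ["linear", "log", "rank"])
    def test_zero_maps_to_zero(self, scale):
        assert av.time_transform(0.0, scale, window_times=[0.0, 1.0, 5.0]) == 0.0

    def test_log_example(self):
        assert av.time_transform(99.0, "log") == pytest.approx(2.0)

    def test_rank_preserves_order(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(size=50)
        times[:5] = 0.0
        y = av.time_transform(times, "rank", window_times=times)
        order = np.argsort(times, kind="stable")
        assert np.all(np.diff(np.asarray(times)[order]) >= 0)
        assert np.all(np.diff(np.asarray(y)[order]) >= 0)
        # strictly increasing in t: distinct times get distinct ranks
        assert len(np.unique(y)) == len(np.unique(times))

    def test_negative_time_rejected(self):
        with pytest.raises(av.ValidationError):
            av.time_transform(-1.0, "linear")


class TestLayoutTree:
    def test_two_tip_tree(self):
        ts = av.simulate(av.SimConfig(n_samples=2, n_intervals=1, sequence_length=5.0, seed=0))
        tree = av.tree_at(ts, 0.0)
        frame = av.layout_tree(tree, ts)
        root = tree.roots[0]
        tips = sorted(v for v in frame.node_x if v != root)
        assert [frame.node_x[t] for t in tips] == [0.0, 1.0]
        assert frame.node_x[root] == 0.5
        assert frame.node_y[root] == ts.nodes.time[root]

    def test_f1_internal_x_is_child_mean(self, f1):
        tree = av.extract_window(f1, FULL)[0]
        frame = av.layout_tree(tree, f1)
        assert frame.tip_order == [0, 1, 2]
        assert frame.node_x[3] == pytest.approx((frame.node_x[0] + frame.node_x[1]) / 2)
        assert frame.node_x[4] == pytest.approx((frame.node_x[3] + frame.node_x[2]) / 2)

    @pytest.mark.parametrize("scale", ["linear", "log", "rank"])
    @pytest.mark.parametrize("order", ["fixed_sample_order", "ladderized"])
    def test_invariants_on_random_trees(self, scale, order):
        """y strictly increases child -> parent; internal x bracketed by
        children; tips have distinct x."""
        for seed in range(8):
            ts = random_fixture(seed, mode="linked")
            config = av.LayoutConfig(time_scale=scale, tip_order=order)
            trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
            frames, _ = av.layout_window(trees, ts, config)
            for frame, tree in zip(frames, trees):
                children = tree.children_map()
                for v in frame.node_x:
                    p = tree.parent[v]
                    if p != av.NONE:
                        assert frame.node_y[p] > frame.node_y[v]
                    kids = children.get(v, [])
                    if kids:
                        xs = [frame.node_x[k] for k in kids]
                        assert min(xs) <= frame.node_x[v] <= max(xs)
                tip_x = [frame.node_x[t] for t in frame.tip_order]
                assert len(set(tip_x)) == len(tip_x)

    def test_metadata_tip_order(self, f1):
        tree = av.extract_window(f1, FULL)[0]
        frame = av.layout_tree(tree, f1, av.LayoutConfig(tip_order="metadata:population"))
        # AFR sample (2) sorts before the EUR samples (0, 1)
        assert frame.tip_order == [2, 0, 1]


class TestLayoutWindow:
    def test_f1_uniform_slots_and_axis(self, f1):
        trees = av.extract_window(f1, FULL)
        frames, axis = av.layout_window(trees, f1)
        assert frames[0].x_domain == (0.0, 0.5)
        assert frames[1].x_domain == (0.5, 1.0)
        np.testing.assert_allclose(axis.canvas, [0, 0.5, 1.0])
        np.testing.assert_allclose(axis.genomic, [0, 5.0, 10.0])

    def test_f1_genomic_equals_uniform_for_equal_lengths(self, f1):
        trees = av.extract_window(f1, FULL)
        u, _ = av.layout_window(trees, f1, av.LayoutConfig(slot_mode="uniform"))
        g, _ = av.layout_window(trees, f1, av.LayoutConfig(slot_mode="genomic"))
        for fu, fg in zip(u, g):
            assert fu.x_domain == fg.x_domain

    def test_genomic_slots_proportional(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(
            "start,end,newick,depth\n"
            '0,1,"(A:1,B:1);",1\n'
            '1,10,"(A:1,B:1);",1\n'
        )
        ts = av.load_csv_genealogies(str(p))
        trees = av.extract_window(ts, av.GenomicInterval(0, 10))
        frames, _ = av.layout_window(trees, ts, av.LayoutConfig(slot_mode="genomic"))
        assert frames[0].x_domain == (0.0, pytest.approx(0.1))
        assert frames[1].x_domain == (pytest.approx(0.1), 1.0)

    def test_gap_fraction_reserved(self, f1):
        trees = av.extract_window(f1, FULL)
        frames, _ = av.layout_window(trees, f1, av.LayoutConfig(tree_gap_fraction=0.2))
        # each slot of nominal width 0.5 shrinks by 0.2 * 0.5 total
        assert frames[0].x_domain == (pytest.approx(0.05), pytest.approx(0.45))
        assert frames[1].x_domain == (pytest.approx(0.55), pytest.approx(0.95))

    def test_shared_y_domain_is_tight(self):
        ts = random_fixture(4, mode="independent")
        trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
        frames, _ = av.layout_window(trees, ts)
        top = frames[0].y_domain[1]
        assert all(f.y_domain == (0.0, top) for f in frames)
        maxima = [max(f.node_y.values()) for f in frames]
        assert all(m <= top + 1e-12 for m in maxima)
        assert max(maxima) == pytest.approx(top)

    def test_empty_window_rejected(self, f1):
        with pytest.raises(av.ValidationError):
            av.layout_window([], f1)

    def test_bit_identical_determinism(self, f1):
        trees = av.extract_window(f1, FULL)
        a, _ = av.layout_window(trees, f1)
        b, _ = av.layout_window(av.extract_window(f1, FULL), f1)
        for fa, fb in zip(a, b):
            assert fa.node_x == fb.node_x and fa.node_y == fb.node_y
            assert fa.tip_order == fb.tip_order
            assert [s.points for s in fa.segments] == [s.points for s in fb.segments]

    def test_fixed_sample_order_stable_across_trees(self):
        """Every sample keeps the same within-slot relative x in all trees."""
        ts = random_fixture(6, mode="linked")
        trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
        frames, _ = av.layout_window(trees, ts)
        rel = None
        for frame in frames:
            left, right = frame.x_domain
            cur = {
                s: (frame.node_x[s] - left) / (right - left)
                for s in frame.tip_order
            }
            if rel is None:
                rel = cur
            else:
                assert cur.keys() == rel.keys()
                for s in cur:
                    assert cur[s] == pytest.approx(rel[s])
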