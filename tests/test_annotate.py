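"""Palettes, search, subsetting, mutation placement, BED overlay."""

import numpy as np
import pandas as pd
import pytest

import argview as av
from .conftest import random_fixture

FULL = av.GenomicInterval(0, 10)


class TestAssignColors:
    def test_f1_lexicographic(self, f1):
        pal = av.assign_colors(f1.metadata, "population")
        assert pal.labels == ["AFR", "EUR"]
        assert pal.color_index == [0, 1]

    def test_single_category(self):
        meta = pd.DataFrame({"grp": ["X", "X"]}, index=[0, 1])
        pal = av.assign_colors(meta, "grp")
        assert pal.labels == ["X"] and pal.color_index == [0]

    def test_fifteen_categories_wrap_mod_12(self):
        meta = pd.DataFrame({"grp": [f"c{i:02d}" for i in range(15)]}, index=range(15))
        pal = av.assign_colors(meta, "grp")
        assert pal.color_index == [i % 12 for i in range(15)]

    def test_numeric_column_rejected(self):
        meta = pd.DataFrame({"age": [1.0, 2.0]}, index=[0, 1])
        with pytest.raises(av.ValidationError, match="numeric"):
            av.assign_colors(meta, "age")

    def test_unknown_column(self, f1):
        with pytest.raises(av.ValidationError, match="unknown"):
            av.assign_colors(f1.metadata, "nope")

    def test_row_order_invariance(self):
        vals = ["b", "a", "c", "a", "b"]
        m1 = pd.DataFrame({"g": vals}, index=range(5))
        m2 = pd.DataFrame({"g": vals[::-1]}, index=range(5))
        p1, p2 = av.assign_colors(m1, "g"), av.assign_colors(m2, "g")
        assert p1.labels == p2.labels and p1.color_index == p2.color_index


class TestSearchSamples:
    def test_exact(self, f1):
        assert av.search_samples(f1.metadata, "population", "EUR") == [0, 1]

    def test_substring_case_insensitive(self, f1):
        assert av.search_samples(f1.metadata, "population", "eu", "substring") == [0, 1]

    def test_no_match_is_empty(self, f1):
        assert av.search_samples(f1.metadata, "population", "eur") == []


class TestSubsetSimplify:
    def test_f1_cherry(self, f1):
        tree = av.extract_window(f1, FULL)[0]
        sub = av.subset_simplify(tree, f1, {0, 1})
        assert sub.roots == [3]
        assert f1.nodes.time[sub.roots[0]] == 1.0
        assert sub.parent[0] == 3 and sub.parent[1] == 3
        assert sub.parent[2] == av.NONE

    def test_all_samples_identity(self, f1):
        tree = av.extract_window(f1, FULL)[0]
        sub = av.subset_simplify(tree, f1, [0, 1, 2])
        np.testing.assert_array_equal(sub.parent, tree.parent)

    def test_rejects_non_sample_and_empty(self, f1):
        tree = av.extract_window(f1, FULL)[0]
        with pytest.raises(av.ValidationError):
            av.subset_simplify(tree, f1, {4})
        with pytest.raises(av.ValidationError):
            av.subset_simplify(tree, f1, set())

    def test_tmrca_preserved_random_pairs(self):
        """Pairwise TMRCAs are untouched by simplification."""
        rng = np.random.default_rng(2)
        checked = 0
        for seed in range(10):
            ts = random_fixture(seed, mode="independent")
            samples = [int(s) for s in ts.samples]
            if len(samples) < 3:
                continue
            tree = av.tree_at(ts, float(rng.uniform(0, ts.sequence_length)))
            for _ in range(30):
                size = int(rng.integers(2, len(samples) + 1))
                chosen = list(rng.choice(samples, size=size, replace=False))
                sub = av.subset_simplify(tree, ts, chosen)
                i, j = rng.choice(chosen, size=2, replace=False)
                t_full = ts.nodes.time[tree.mrca(ts, [int(i), int(j)])]
                t_sub = ts.nodes.time[sub.mrca(ts, [int(i), int(j)])]
                assert t_full == t_sub
                checked += 1
        assert checked >= 200

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ts = random_fixture(1, mode="independent")
        samples = [int(s) for s in ts.samples]
        tree = av.tree_at(ts, 1.0)
        chosen = list(rng.choice(samples, size=max(2, len(samples) // 2), replace=False))
        once = av.subset_simplify(tree, ts, chosen)
        twice = av.subset_simplify(once, ts, chosen)
        np.testing.assert_array_equal(once.parent, twice.parent)
        assert once.roots == twice.roots


class TestPlaceMutations:
    def test_f1_midpoint_anchor(self, f1):
        trees = av.extract_window(f1, FULL)
        frames, _ = av.layout_window(trees, f1)
        marks = av.place_mutations(f1, frames[0])
        assert len(marks) == 1
        mk = marks[0]
        assert mk.node == 0 and mk.position == 2.0
        assert mk.x == frames[0].node_x[0]
        assert mk.y == pytest.approx(0.5)  # midpoint of times 0 and 1 (linear)
        assert not mk.above_root

    def test_out_of_interval_skipped(self, f1):
        trees = av.extract_window(f1, FULL)
        frames, _ = av.layout_window(trees, f1)
        assert av.place_mutations(f1, frames[1]) == []

    def test_multiple_on_branch_spread_evenly(self, f1):
        f1.sites = av.SiteTable.from_rows([(1.0, "A"), (2.0, "A"), (3.0, "A")])
        f1.mutations = av.MutationTable.from_rows([(0, 0, "G"), (1, 0, "C"), (2, 0, "T")])
        frames, _ = av.layout_window(av.extract_window(f1, FULL), f1)
        marks = av.place_mutations(f1, frames[0])
        ys = [m.y for m in sorted(marks, key=lambda m: m.position)]
        assert ys == [pytest.approx(0.25), pytest.approx(0.5), pytest.approx(0.75)]

    def test_root_mutation_flagged(self, f1):
        f1.mutations = av.MutationTable.from_rows([(0, 4, "G")])  # above the root
        frames, _ = av.layout_window(av.extract_window(f1, FULL), f1)
        marks = av.place_mutations(f1, frames[0])
        assert len(marks) == 1 and marks[0].above_root

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conservation_over_full_genome(self, seed):
        """Total marks across all frames equals the mutation row count."""
        ts = random_fixture(seed, mode="linked", mutations=25)
        trees = av.extract_window(ts, av.GenomicInterval(0, ts.sequence_length))
        frames, _ = av.layout_window(trees, ts)
        total = sum(len(av.place_mutations(ts, f)) for f in frames)
        in_range = sum(
            1 for p in ts.sites.position[ts.mutations.site_id]
            if 0 <= p < ts.sequence_length
        )
        assert total == in_range == 25


class TestBedTrack:
    def test_covered_trees(self, f1, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr\t2\t7\tgeneX\n")
        feats = av.load_bed_track(str(bed), f1)
        assert len(feats) == 1
        assert feats[0].name == "geneX"
        assert feats[0].covered_trees == [0, 1]

    def test_half_open_boundary(self, f1, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr\t0\t5\n")
        feats = av.load_bed_track(str(bed), f1)
        assert feats[0].covered_trees == [0]

    def test_outside_dropped_with_warning(self, f1, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr\t20\t30\tfar\n")
        with pytest.warns(UserWarning, match="dropped"):
            feats = av.load_bed_track(str(bed), f1)
        assert feats == []

    @pytest.mark.parametrize("line", ["chr\t5", "chr\t7\t7"])
    def test_malformed_rejected(self, f1, tmp_path, line):
        bed = tmp_path / "t.bed"
        bed.write_text(line + "\n")
        with pytest.raises(av.ValidationError):
            av.load_bed_track(str(bed), f1)

    def test_covered_indices_consecutive(self, tmp_path):
        ts = random_fixture(9, mode="independent")
        bed = tmp_path / "t.bed"
        L = ts.sequence_length
        bed.write_text(f"chr\t{L*0.2}\t{L*0.8}\n")
        feats = av.load_bed_track(str(bed), ts)
        covered = feats[0].covered_trees
        assert covered == list(range(covered[0], covered[-1] + 1))
        # exactness: covered trees are those whose interval intersects
        for tree in av.sweep(ts):
            expect = tree.interval.intersects(feats[0].interval)
            assert (tree.index in covered) == expect
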