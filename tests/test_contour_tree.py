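"""Contour tree construction, branch decomposition, simplification and
segmentation."""

import numpy as np
import pytest

import topolight as tl
from topolight.contour_tree import build_contour_tree, neighbor_table

from conftest import oracle_critical_sets, tree_critical_sets


class TestMergeTree:
    def test_monotone_ramp_has_single_arc(self):
        field = tl.ScalarField(np.array([0.0, 1.0, 2.0, 3.0]))
        jt = tl.build_merge_tree(field, "ascending")
        nodes, arcs = jt.reduced()
        assert nodes == [0, 3]
        assert arcs == [(0, 3)] or arcs == [(3, 0)]

    def test_two_blob_join_tree_leaves_and_saddle(self, two_blob_5x5):
        jt = tl.build_merge_tree(two_blob_5x5, "ascending")
        leaves = set(jt.leaves())
        flat = two_blob_5x5.flat()
        assert {round(float(flat[v]), 1) for v in leaves} == {9.0, 8.0}
        counts = jt.child_counts()
        saddles = {round(float(flat[v]), 1) for v in np.nonzero(counts >= 2)[0]}
        assert saddles == {5.0}

    def test_split_tree_leaf_is_minimum(self, two_blob_5x5):
        st = tl.build_merge_tree(two_blob_5x5, "descending")
        flat = two_blob_5x5.flat()
        assert {round(float(flat[v]), 1) for v in st.leaves()} == {2.4}

    def test_rejects_nonfinite_and_degenerate(self):
        with pytest.raises(ValueError):
            tl.ScalarField(np.array([0.0, np.nan]))
        with pytest.raises(ValueError):
            tl.build_merge_tree(tl.ScalarField(np.ones((1, 1, 1))), "ascending")
        field = tl.ScalarField(np.arange(4.0))
        with pytest.raises(ValueError):
            tl.build_merge_tree(field, "sideways")
        with pytest.raises(ValueError):
            tl.build_merge_tree(field, "ascending", connectivity=18)

    def test_neighbor_table_shapes(self):
        nbr6 = neighbor_table((3, 3, 3), 6)
        nbr26 = neighbor_table((3, 3, 3), 26)
        assert nbr6.shape == (27, 6) and nbr26.shape == (27, 26)
        center = 1 + 3 * (1 + 3 * 1)
        assert (nbr6[center] >= 0).all()
        corner_valid = (nbr26[0] >= 0).sum()
        assert corner_valid == 7  # 2x2x2 block minus itself


class TestCombine:
    def test_ramp_contour_tree_single_arc(self):
        field = tl.ScalarField(np.arange(4.0))
        ct = build_contour_tree(field)
        assert ct.n_nodes == 2 and len(ct.arcs) == 1
        kinds = {nd.kind for nd in ct.nodes}
        assert kinds == {"minimum", "maximum"}

    def test_two_blob_three_leaves_one_saddle(self, two_blob_tree):
        ct = two_blob_tree
        leaves = ct.leaves()
        assert len(leaves) == 3
        assert sorted(round(nd.value, 1) for nd in leaves) == [2.4, 8.0, 9.0]
        saddles = ct.saddles()
        assert [round(nd.value, 1) for nd in saddles] == [5.0]
        assert len(ct.arcs) == ct.n_nodes - 1

    def test_interior_max_boundary_min_is_path_tree(self):
        field = tl.multi_blob_volume((9, 9, 9), [((4.0, 4.0, 4.0), 5.0, 1.5)])
        ct = build_contour_tree(field)
        bd = tl.simplify_tree(tl.decompose_branches(ct), "persistence",
                              threshold=0.1)
        assert bd.n_branches == 1

    def test_constant_field_degenerates_to_single_node(self):
        ct = build_contour_tree(tl.ScalarField(np.full((3, 3, 3), 7.0)))
        assert ct.n_nodes == 1 and len(ct.arcs) == 0
        bd = tl.decompose_branches(ct)
        assert bd.n_branches == 1
        assert bd.root.voxel_count == 27

    def test_combine_rejects_mismatched_fields(self):
        f1 = tl.ScalarField(np.arange(8.0).reshape(2, 2, 2))
        f2 = tl.ScalarField(np.arange(8.0)[::-1].copy().reshape(2, 2, 2))
        jt = tl.build_merge_tree(f1, "ascending")
        st = tl.build_merge_tree(f2, "descending")
        with pytest.raises(ValueError):
            tl.combine_trees(jt, st)


class TestOracleEquivalence:
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_grids_match_level_set_oracle(self, connectivity):
        """Leaves and saddles (as vertex sets, hence values too) match the
        component-counting oracle on random distinct-valued grids."""
        rng = np.random.default_rng(20210 + connectivity)
        for _ in range(30):
            dims = tuple(int(d) for d in rng.integers(2, 6, size=3))
            vals = rng.permutation(np.prod(dims)).astype(float).reshape(dims)
            ct = build_contour_tree(tl.ScalarField(vals), connectivity)
            assert tree_critical_sets(ct) == oracle_critical_sets(vals, connectivity)
            assert len(ct.arcs) == ct.n_nodes - 1


class TestBranchDecomposition:
    def test_single_arc_tree_single_root_branch(self):
        ct = build_contour_tree(tl.ScalarField(np.arange(5.0)))
        bd = tl.decompose_branches(ct)
        assert bd.n_branches == 1
        assert bd.root.parent_id is None and not bd.root.child_ids

    def test_two_blob_pairing_is_highest_persistence(self, two_blob_decomposition):
        bd = two_blob_decomposition
        assert bd.n_branches == 2
        root, child = bd.root, bd.get(bd.root.child_ids[0])
        assert {round(bd.node_value(root.top_node_id), 1),
                round(bd.node_value(root.bottom_node_id), 1)} == {9.0, 2.4}
        assert round(bd.node_value(child.top_node_id), 1) == 8.0
        assert round(bd.node_value(child.bottom_node_id), 1) == 5.0
        assert child.parent_id == root.id
        assert bd.persistence(child.id) == pytest.approx(3.0)

    def test_nested_chain_depths(self, nested_chain_pipeline):
        _, bd, _, _ = nested_chain_pipeline
        assert sorted(bd.depths().values()) == [0, 1, 2]

    def test_empty_tree_rejected(self, two_blob_tree):
        with pytest.raises(ValueError):
            tl.decompose_branches(two_blob_tree, "curvature")

    @pytest.mark.parametrize("measure", ["persistence", "volume",
                                         "hypervolume", "triangle_area"])
    def test_every_voxel_in_exactly_one_branch(self, two_blob_5x5, measure):
        ct = build_contour_tree(two_blob_5x5)
        bd = tl.decompose_branches(ct, measure)
        counts = np.bincount(bd.vertex_branch)
        assert counts.sum() == two_blob_5x5.n_vertices
        for b in bd.branches:
            assert b.voxel_count == counts[b.id]


class TestSimplify:
    def test_zero_threshold_is_identity(self, two_blob_decomposition):
        out = tl.simplify_tree(two_blob_decomposition, "persistence", threshold=0.0)
        assert out.n_branches == two_blob_decomposition.n_branches

    def test_two_blob_threshold_four_prunes_child(self, two_blob_decomposition):
        out = tl.simplify_tree(two_blob_decomposition, "persistence", threshold=4.0)
        assert out.n_branches == 1
        assert out.root.voxel_count == 25

    def test_infinite_threshold_leaves_root_only(self, nested_chain_pipeline):
        _, bd, _, _ = nested_chain_pipeline
        out = tl.simplify_tree(bd, "persistence", threshold=np.inf)
        assert out.n_branches == 1
        assert out.root.voxel_count == bd.field.n_vertices

    def test_branch_count_monotone_in_threshold(self):
        field = tl.add_noise(
            tl.multi_blob_volume((14, 14, 14),
                                 [((4.5, 7.0, 7.0), 9.0, 1.8),
                                  ((9.5, 7.0, 7.0), 8.0, 1.8)]),
            sigma=0.15, seed=4)
        bd = tl.decompose_branches(build_contour_tree(field))
        counts = [
            tl.simplify_tree(bd, "persistence", threshold=t).n_branches
            for t in (0.0, 0.1, 0.5, 1.0, 4.0, np.inf)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1

    def test_noisy_field_recovers_clean_topology_at_target_count(self):
        clean = tl.multi_blob_volume((14, 14, 14),
                                     [((4.5, 7.0, 7.0), 9.0, 1.8),
                                      ((9.5, 7.0, 7.0), 8.0, 1.8)])
        bd_clean = tl.simplify_tree(
            tl.decompose_branches(build_contour_tree(clean)),
            "persistence", threshold=0.2)
        noisy = tl.add_noise(clean, sigma=0.05, seed=11)
        bd_noisy = tl.simplify_tree(
            tl.decompose_branches(build_contour_tree(noisy)),
            "persistence", target_branch_count=bd_clean.n_branches)
        assert bd_noisy.n_branches == bd_clean.n_branches
        assert sorted(bd_noisy.depths().values()) == sorted(bd_clean.depths().values())

    def test_target_above_count_warns_and_returns_input(self, two_blob_decomposition):
        with pytest.warns(UserWarning):
            out = tl.simplify_tree(two_blob_decomposition, "persistence",
                                   target_branch_count=10)
        assert out.n_branches == two_blob_decomposition.n_branches

    def test_remaining_leaves_meet_threshold(self, nested_chain_pipeline):
        _, bd, _, _ = nested_chain_pipeline
        out = tl.simplify_tree(bd, "persistence", threshold=3.0)
        for b in out.branches:
            if b.parent_id is not None and not b.child_ids:
                assert out.persistence(b.id) >= 3.0


class TestSegmentation:
    def test_single_branch_labels_everything_root(self):
        field = tl.ScalarField(np.arange(24.0).reshape(4, 3, 2))
        bd = tl.decompose_branches(build_contour_tree(field))
        seg = tl.segment_field(field, bd)
        assert set(np.unique(seg.labels)) == {bd.root.id}

    def test_two_blob_child_region_above_saddle(self, two_blob_5x5,
                                                two_blob_decomposition):
        seg = tl.segment_field(two_blob_5x5, two_blob_decomposition)
        child = two_blob_decomposition.root.child_ids[0]
        vals = two_blob_5x5.values[seg.labels == child]
        # child region: strictly above the saddle (5.0), within blob 2
        assert vals.size > 0 and (vals > 5.0).all() and (vals <= 8.0).all()

    def test_labels_partition_volume(self, three_blob_pipeline):
        field, bd, seg, _ = three_blob_pipeline
        sizes = [seg.region_size(b) for b in bd.branch_ids]
        assert sum(sizes) == field.n_vertices
        assert all(s > 0 for s in sizes)

    def test_segmentation_rejects_foreign_field(self, two_blob_decomposition):
        other = tl.ScalarField(np.zeros((5, 5, 1)))
        with pytest.raises(ValueError):
            tl.segment_field(other, two_blob_decomposition)

    def test_nested_regions_contained_in_parent_superlevel(self,
                                                           nested_chain_pipeline):
        field, bd, seg, attrs = nested_chain_pipeline
        depths = bd.depths()
        for b in bd.branches:
            if b.parent_id is None:
                continue
            region = seg.labels == b.id
            parent_saddle = attrs[b.parent_id].saddle_value
            assert (field.values[region] > parent_saddle).all()
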