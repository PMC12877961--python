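"""Branch decomposition, lengths, Sholl profiles, comparison arithmetic, skeletons."""

import math

import numpy as np
import pytest

from golgitrace import (
    TraceCostParams,
    branch_length_distribution,
    branch_segments,
    compare_morphometry,
    fold_change,
    label_components,
    length_by_type,
    measure,
    percent_change,
    retype_subtree,
    select_neuron,
    skeletonize_to_swc,
    sholl_profile,
    threshold_volume,
    total_length,
)
from golgitrace.phantom import PhantomSpec, generate_tree, make_phantom, voxelize_tree

from conftest import make_mask, make_tree, make_volume, straight_tree, y_tree


class TestBranchSegments:
    def test_unbranched_path_is_one_branch(self):
        assert len(branch_segments(straight_tree(10))) == 1

    def test_y_tree_has_three_branches(self):
        assert len(branch_segments(y_tree())) == 3

    @pytest.mark.parametrize("b", [0, 1, 3, 5, 8])
    def test_binary_tree_count_closed_form(self, b):
        # root of degree 1 with b bifurcations → 2b + 1 branches
        tree = generate_tree(PhantomSpec(rng_seed=b + 1, n_bifurcations=b))
        assert len(branch_segments(tree)) == 2 * b + 1


class TestLengths:
    def test_collinear_total(self):
        tree = straight_tree(11, step=10.0)
        assert total_length(tree) == pytest.approx(100.0)
        assert branch_length_distribution(tree) == pytest.approx([100.0])

    def test_y_tree_distribution(self):
        tree = y_tree(stem=50.0, arm=50.0)
        assert total_length(tree) == pytest.approx(150.0)
        assert sorted(branch_length_distribution(tree)) == pytest.approx([50.0, 50.0, 50.0])

    def test_length_conservation(self):
        tree = generate_tree(PhantomSpec(rng_seed=5))
        t = total_length(tree)
        assert sum(branch_length_distribution(tree)) == pytest.approx(t, rel=1e-6)
        assert sum(length_by_type(tree).values()) == pytest.approx(t, rel=1e-6)


class TestRetype:
    def test_retype_root_retypes_whole_tree(self):
        tree = retype_subtree(straight_tree(5), 1, 2)
        assert set(tree.nodes["stype"]) == {2}

    def test_retype_leaf_touches_one_node(self):
        tree = straight_tree(5)
        leaf = int(tree.nodes["id"].iloc[-1])
        out = retype_subtree(tree, leaf, 2)
        assert (out.nodes["stype"] == 2).sum() == 1

    def test_retyped_arm_length_moves_between_types(self):
        tree = y_tree(stem=50.0, arm=50.0)
        # retype one arm: first node after the fork
        fork_children = [
            n for n in branch_segments(tree)[1]
        ]
        arm_root = fork_children[1]
        out = retype_subtree(tree, arm_root, 2)
        assert length_by_type(out, 2) == pytest.approx(50.0)
        assert length_by_type(out, 3) + length_by_type(out, 2) == pytest.approx(
            total_length(tree) - length_by_type(out, 1), rel=1e-6
        )

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            retype_subtree(straight_tree(3), 99, 2)


def analytic_crossings(p, q, center, r):
    """Sphere-crossing count for one straight segment (convex distance)."""
    d = q - p
    f = p - center
    a = float(d @ d)
    if a == 0:
        return 0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = b * b - 4 * a * c
    if disc <= 0:
        return 0  # miss or tangency
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    # a root at t=0 belongs to the outgoing step; one at t=1 to the next edge
    return sum(1 for t in roots if 0.0 <= t < 1.0)


class TestSholl:
    def test_single_radial_branch(self):
        tree = straight_tree(11, step=10.0)  # 100 μm along +x from the soma
        prof = sholl_profile(tree, (0, 0, 0), [20, 50, 80, 120])
        assert prof.counts == (1, 1, 1, 0)

    def test_y_tree_counts(self):
        tree = y_tree(stem=50.0, arm=50.0)
        prof = sholl_profile(tree, (0, 0, 0), [25, 75])
        assert prof.counts == (1, 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_analytic_oracle_on_phantom_trees(self, seed):
        tree = generate_tree(PhantomSpec(rng_seed=seed))
        center = tree.soma_position()
        radii = [10.0 * i for i in range(1, 15)]
        prof = sholl_profile(tree, center, radii)
        pos = tree.positions()
        parents = tree.parent_map()
        for r, got in zip(radii, prof.counts):
            want = sum(
                analytic_crossings(pos[pid], pos[nid], center, r)
                for nid, pid in parents.items()
                if pid != -1
            )
            assert got == want, f"radius {r}"

    def test_counts_vanish_beyond_farthest_tip(self):
        tree = y_tree()
        prof = sholl_profile(tree, (0, 0, 0), [500.0])
        assert prof.counts == (0,)


class TestComparisonArithmetic:
    @pytest.mark.parametrize(
        "raw,revised,pct",
        [
            (19, 30, 58),        # branch count, visual-cortex worked example
            (1553, 2896, 86),    # total branch length μm
            (23, 30, 30),        # somatosensory branch count
            (1473, 2595, 76),    # somatosensory dendritic length
            (47, 172, 266),      # axon length
            (48, 52, 8),
            (5779, 6535, 13),
            (16, 32, 100),
            (1293, 3325, 157),
            (25, 30, 20),
            (2457, 3575, 46),
        ],
    )
    def test_percent_change_matches_reported_values(self, raw, revised, pct):
        assert percent_change(raw, revised) == pct

    def test_fold_change_one_decimal(self):
        assert fold_change(47, 172) == pytest.approx(3.7)

    def test_zero_raw_reports_fold_only(self):
        assert percent_change(0, 5) is None
        assert fold_change(0, 5) is None

    def test_identical_trees_give_zero_change(self):
        tree = y_tree()
        cmp = compare_morphometry(tree, tree)
        assert all(v == 0 for v in cmp.percent_change.values() if v is not None)
        assert all(v == pytest.approx(1.0) for v in cmp.fold_change.values() if v is not None)

    def test_superset_tree_changes_nonnegative(self):
        raw = y_tree(stem=50.0, arm=30.0)
        revised = y_tree(stem=50.0, arm=50.0)
        cmp = compare_morphometry(raw, revised)
        assert cmp.revised.total_length >= cmp.raw.total_length
        for a, b in zip(cmp.raw.sholl.counts, cmp.revised.sholl.counts):
            assert b >= a


def extract_neuron(vol, soma_xyz, threshold=220):
    lab = label_components(threshold_volume(vol, threshold))
    return select_neuron(lab, soma_xyz, snap_radius=8.0)


class TestSkeletonize:
    def test_straight_tube_single_branch_length(self):
        spec = PhantomSpec(
            shape=(24, 44, 240), spacing=(2.5, 1, 1), n_bifurcations=0,
            segment_length=(100.0, 100.0), noise_sd=0.0, gaps_per_100um=0.0,
            n_vessels=0, n_glia=0, n_puncta=0, rng_seed=3,
        )
        tree = generate_tree(spec)
        vol = voxelize_tree(tree, spec)
        soma = tuple(tree.soma_position())
        mask = extract_neuron(vol, soma)
        swc = skeletonize_to_swc(mask, vol, soma, TraceCostParams(), radius_threshold=220)
        assert len(branch_segments(swc)) == 1
        assert total_length(swc) == pytest.approx(100.0, rel=0.05)

    def test_y_phantom_one_bifurcation(self):
        spec = PhantomSpec(
            n_bifurcations=1, noise_sd=0.0, gaps_per_100um=0.0,
            n_vessels=0, n_glia=0, n_puncta=0, rng_seed=8,
        )
        tree = generate_tree(spec)
        vol = voxelize_tree(tree, spec)
        soma = tuple(tree.soma_position())
        swc = skeletonize_to_swc(
            extract_neuron(vol, soma), vol, soma, TraceCostParams(), radius_threshold=220
        )
        assert len(branch_segments(swc)) == 3

    def test_solid_cube_degenerates_gracefully(self):
        grid = np.full((5, 5, 5), 10, dtype=np.uint8)
        grid[1:4, 1:4, 1:4] = 250
        vol = make_volume(grid)
        mask = make_mask(grid >= 250)
        swc = skeletonize_to_swc(mask, vol, (2.0, 2.0, 2.0), TraceCostParams(), radius_threshold=200)
        assert total_length(swc) < math.sqrt(3) * 3  # under the cube diagonal

    def test_empty_mask_rejected(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            skeletonize_to_swc(
                make_mask(np.zeros((3, 3, 3), dtype=bool)), vol, (0, 0, 0),
                TraceCostParams(i_max=1),
            )

    def test_phantom_branch_count_and_length_recovered(self):
        # length is recovered within ±5% on every phantom; branch count
        # within ±10% on average (an occasional near-merged close-angle
        # junction can add one spurious bifurcation on a single phantom)
        errs = []
        for seed in (2, 5, 9):
            spec = PhantomSpec(rng_seed=seed, gaps_per_100um=0.0,
                               n_vessels=0, n_glia=0, n_puncta=0)
            vol, truth = make_phantom(spec)
            soma = tuple(truth.tree.soma_position())
            swc = skeletonize_to_swc(
                extract_neuron(vol, soma), vol, soma, TraceCostParams(),
                radius_threshold=220,
            )
            b_true = len(branch_segments(truth.tree))
            errs.append(abs(len(branch_segments(swc)) - b_true) / b_true)
            assert total_length(swc) == pytest.approx(total_length(truth.tree), rel=0.05)
        assert np.mean(errs) <= 0.10

    def test_root_is_soma_typed(self):
        tree = generate_tree(PhantomSpec(rng_seed=1, n_bifurcations=1,
                                         gaps_per_100um=0.0, n_vessels=0,
                                         n_glia=0, n_puncta=0))
        spec = PhantomSpec(rng_seed=1, n_bifurcations=1, noise_sd=0.0)
        vol = voxelize_tree(tree, spec)
        soma = tuple(tree.soma_position())
        swc = skeletonize_to_swc(
            extract_neuron(vol, soma), vol, soma, TraceCostParams(), radius_threshold=220
        )
        root_row = swc.nodes.loc[swc.nodes["parent"] == -1]
        assert int(root_row["stype"].iloc[0]) == 1
        assert set(swc.nodes.loc[swc.nodes["parent"] != -1, "stype"]) == {3}


class TestMeasure:
    def test_report_conservation_invariant(self):
        tree = generate_tree(PhantomSpec(rng_seed=6))
        rep = measure(tree)
        assert rep.total_length == pytest.approx(sum(rep.branch_lengths), rel=1e-6)
        assert rep.total_length == pytest.approx(sum(rep.length_by_type.values()), rel=1e-6)
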