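"""Cost field, geodesic tracing, marker attachment, radius estimation, repair."""

import math

import networkx as nx
import numpy as np
import pytest

from golgitrace import (
    BinaryMask,
    Marker,
    MarkerSet,
    TraceCostParams,
    attach_marker,
    build_cost_field,
    estimate_radii,
    label_components,
    repair_neuron,
    threshold_volume,
    trace_path,
)
from golgitrace.gap_repair import TracePath

from conftest import make_mask, make_volume


class TestCostField:
    def test_max_intensity_costs_one(self):
        vol = make_volume(np.full((2, 2, 2), 255))
        np.testing.assert_allclose(build_cost_field(vol, TraceCostParams(i_max=255)), 1.0)

    def test_zero_intensity_costs_e_lambda(self):
        vol = make_volume(np.zeros((1, 1, 1)))
        c = build_cost_field(vol, TraceCostParams(lambda_=10, gamma=2, i_max=255))
        assert c[0, 0, 0] == pytest.approx(math.exp(10.0))

    def test_half_intensity_closed_form(self):
        # (1 - 1/2)^2 * 10 = 2.5
        vol = make_volume(np.full((1, 1, 1), 100))
        c = build_cost_field(vol, TraceCostParams(lambda_=10, gamma=2, i_max=200))
        assert c[0, 0, 0] == pytest.approx(math.exp(2.5))

    def test_monotone_in_intensity(self):
        vol = make_volume(np.arange(256).reshape(1, 16, 16))
        c = build_cost_field(vol, TraceCostParams(i_max=255))
        assert (np.diff(c.ravel()) <= 0).all()

    def test_zero_imax_rejected(self):
        with pytest.raises(ValueError):
            TraceCostParams(i_max=0)


def nx_dijkstra_cost(vol, cost, start, goal):
    """Independent shortest-path oracle on the 26-neighbour voxel graph."""
    g = nx.Graph()
    nz, ny, nx_ = cost.shape
    dz, dy, dx = vol.spacing
    for z in range(nz):
        for y in range(ny):
            for x in range(nx_):
                for oz in (-1, 0, 1):
                    for oy in (-1, 0, 1):
                        for ox in (-1, 0, 1):
                            if (oz, oy, ox) == (0, 0, 0):
                                continue
                            v = (z + oz, y + oy, x + ox)
                            if not (0 <= v[0] < nz and 0 <= v[1] < ny and 0 <= v[2] < nx_):
                                continue
                            step = math.sqrt((oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2)
                            w = step * 0.5 * (cost[z, y, x] + cost[v])
                            g.add_edge((z, y, x), v, weight=w)
    return nx.dijkstra_path_length(g, start, goal)


class TestTracePath:
    def test_uniform_volume_axis_path_is_straight(self):
        vol = make_volume(np.full((3, 3, 9), 200), spacing=(2.5, 1, 1))
        cost = build_cost_field(vol, TraceCostParams(i_max=200))
        tp = trace_path(vol, cost, (1, 1, 0), (1, 1, 8))
        assert tp.length == pytest.approx(8.0)
        assert all(v[:2] == (1, 1) for v in tp.voxels)

    @pytest.mark.parametrize("seed", range(8))
    def test_cost_matches_exhaustive_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 256, (5, 5, 5))
        vol = make_volume(grid, spacing=(2.0, 1.0, 1.5))
        cost = build_cost_field(vol, TraceCostParams(i_max=255))
        start, goal = (0, 0, 0), (4, 4, 4)
        tp = trace_path(vol, cost, start, goal)
        assert tp.cost == pytest.approx(nx_dijkstra_cost(vol, cost, start, goal))

    def test_path_stays_inside_bright_l_tube(self):
        grid = np.zeros((3, 12, 12), dtype=np.uint8)
        grid[1, 2, 2:10] = 250   # horizontal arm
        grid[1, 2:10, 9] = 250   # vertical arm
        vol = make_volume(grid)
        cost = build_cost_field(vol, TraceCostParams(i_max=250))
        tp = trace_path(vol, cost, (1, 2, 2), (1, 9, 9))
        assert all(grid[v] >= 250 for v in tp.voxels)

    def test_path_invariants(self):
        rng = np.random.default_rng(11)
        vol = make_volume(rng.integers(0, 256, (4, 6, 6)))
        cost = build_cost_field(vol, TraceCostParams(i_max=255))
        tp = trace_path(vol, cost, (0, 0, 0), (3, 5, 5))
        assert len(set(tp.voxels)) == len(tp.voxels)
        for a, b in zip(tp.voxels, tp.voxels[1:]):
            assert max(abs(a[i] - b[i]) for i in range(3)) == 1
        euclid = math.dist((0, 0, 0), (3, 5, 5))
        assert tp.length >= euclid - 1e-9

    def test_determinism(self):
        rng = np.random.default_rng(4)
        vol = make_volume(rng.integers(0, 256, (4, 5, 5)))
        cost = build_cost_field(vol, TraceCostParams(i_max=255))
        a = trace_path(vol, cost, (0, 0, 0), (3, 4, 4))
        b = trace_path(vol, cost, (0, 0, 0), (3, 4, 4))
        assert a.voxels == b.voxels

    def test_identical_endpoints_rejected(self):
        vol = make_volume(np.zeros((2, 2, 2)))
        cost = build_cost_field(vol, TraceCostParams(i_max=1))
        with pytest.raises(ValueError):
            trace_path(vol, cost, (0, 0, 0), (0, 0, 0))


class TestAttachMarker:
    def test_marker_on_structure_voxel(self):
        grid = np.zeros((3, 3, 3), dtype=bool)
        grid[1, 2, 2] = True
        assert attach_marker(make_mask(grid), (2.0, 2.0, 1.0)) == (1, 2, 2)

    def test_equidistant_tie_breaks_lexicographically(self):
        grid = np.zeros((1, 1, 4), dtype=bool)
        grid[0, 0, 0] = grid[0, 0, 3] = True
        # marker at x=1.5 is equidistant; smaller (z,y,x) wins
        assert attach_marker(make_mask(grid), (1.5, 0.0, 0.0)) == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((5, 6, 6)) < 0.2
        if not grid.any():
            grid[0, 0, 0] = True
        spacing = (2.5, 1.0, 1.0)
        pos = tuple(rng.uniform(0, 5, 3))
        got = attach_marker(BinaryMask(grid, spacing), pos)
        best, bestd = None, np.inf
        for v in map(tuple, np.argwhere(grid)):
            c = (v[2] * spacing[2], v[1] * spacing[1], v[0] * spacing[0])
            d = math.dist(c, pos)
            if d < bestd - 1e-12:
                best, bestd = v, d
        assert got == best

    def test_empty_structure_errors(self):
        with pytest.raises(ValueError):
            attach_marker(make_mask(np.zeros((2, 2, 2), dtype=bool)), (0, 0, 0))


class TestEstimateRadii:
    def test_bright_cylinder_radius_recovered(self):
        # radius-3 μm bright cylinder along x at 1 μm isotropic spacing
        grid = np.zeros((9, 9, 9), dtype=np.uint8)
        zz, yy = np.meshgrid(np.arange(9) - 4, np.arange(9) - 4, indexing="ij")
        disc = zz**2 + yy**2 <= 9
        grid[disc, :] = 240
        vol = make_volume(grid)
        r = estimate_radii(vol, ((4, 4, 4),), T=200)
        assert r[0] == pytest.approx(3.0, abs=0.6)

    def test_background_node_gets_floor(self):
        vol = make_volume(np.zeros((5, 5, 5)), spacing=(2.0, 1.0, 1.0))
        r = estimate_radii(vol, ((2, 2, 2),), T=100)
        assert r[0] == pytest.approx(0.5)  # half the minimum spacing

    def test_lowering_threshold_never_shrinks_radii(self):
        rng = np.random.default_rng(9)
        vol = make_volume(rng.integers(0, 256, (7, 7, 7)))
        path = ((3, 3, 3), (3, 3, 4))
        hi = estimate_radii(vol, path, T=200)
        lo = estimate_radii(vol, path, T=100)
        assert (lo >= hi).all()


def gapped_tube_volume(gap_lo=14, gap_hi=19):
    """Bright 1-voxel-radius tube along x with an erased interval, plus soma blob."""
    grid = np.full((7, 9, 30), 20, dtype=np.uint8)
    grid[2:5, 3:6, 1:27] = 240          # tube
    grid[2:5, 2:7, 1:5] = 240           # soma-ish thickening
    grid[:, :, gap_lo:gap_hi] = 20      # the gap
    return make_volume(grid)


class TestRepairNeuron:
    def _setup(self):
        vol = gapped_tube_volume()
        mask = threshold_volume(vol, 200)
        lab = label_components(mask)
        # soma-side component = the one containing x=2
        keep = lab.label_grid[3, 4, 2]
        base = BinaryMask(lab.label_grid == keep, vol.spacing)
        return vol, base

    def test_terminal_inside_mask_is_noop(self):
        vol, base = self._setup()
        ms = MarkerSet((Marker("branch_terminal", (2.0, 4.0, 3.0)),))
        res = repair_neuron(base, vol, ms, threshold=200)
        assert len(res.paths) == 0
        assert res.report.loc[0, "status"] == "already_connected"
        np.testing.assert_array_equal(res.mask.grid, base.grid)

    def test_gap_bridged_into_single_component(self):
        vol, base = self._setup()
        tip = (26.0, 4.0, 3.0)  # far end of the tube, beyond the gap
        ms = MarkerSet((Marker("branch_terminal", tip),))
        res = repair_neuron(base, vol, ms, threshold=200)
        assert res.report.loc[0, "status"] == "repaired"
        lab = label_components(res.mask)
        assert lab.n_components == 1
        assert res.mask.grid[3, 4, 26]
        assert res.paths[0].length >= 5.0  # at least the gap length

    def test_repaired_mask_is_superset(self):
        vol, base = self._setup()
        ms = MarkerSet((Marker("branch_terminal", (26.0, 4.0, 3.0)),))
        res = repair_neuron(base, vol, ms, threshold=200)
        assert (res.mask.grid | base.grid == res.mask.grid).all()

    def test_two_gaps_two_terminals(self):
        grid = np.full((7, 9, 40), 20, dtype=np.uint8)
        grid[2:5, 3:6, 1:37] = 240
        grid[:, :, 12:16] = 20
        grid[:, :, 25:29] = 20
        vol = make_volume(grid)
        lab = label_components(threshold_volume(vol, 200))
        keep = lab.label_grid[3, 4, 2]
        base = BinaryMask(lab.label_grid == keep, vol.spacing)
        ms = MarkerSet(
            (
                Marker("branch_terminal", (20.0, 4.0, 3.0)),
                Marker("branch_terminal", (36.0, 4.0, 3.0)),
            )
        )
        res = repair_neuron(base, vol, ms, threshold=200)
        assert list(res.report["status"]) == ["repaired", "repaired"]
        assert len(res.paths) == 2
        assert label_components(res.mask).n_components == 1

    def test_failed_trace_reported_and_mask_returned(self):
        vol, base = self._setup()
        # unreachable terminal: pure background far corner with a tiny cost cap
        ms = MarkerSet((Marker("branch_terminal", (29.0, 8.0, 6.0)),))
        res = repair_neuron(base, vol, ms, threshold=200, cap_factor=1e-9)
        assert res.report.loc[0, "status"] == "failed"
        np.testing.assert_array_equal(res.mask.grid, base.grid)
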