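"""Tracing: skeletonization, graph building, morphometrics, rim filtering."""

import math

import numpy as np
import pytest

from angioquant.graph import segment_straightness
from angioquant.synthetic import rasterize_network
from angioquant.tracing import (
    build_vessel_graph,
    center_orientation_distribution,
    circular_sd,
    measure_segment,
    remove_boundary_segments,
    segment_table,
    skeletonize_mask,
    trace_mask,
)

from conftest import make_volume


def _skeleton_volume(coords, shape, spacing=(1.0, 1.0, 1.0)):
    data = np.zeros(shape, dtype=bool)
    for c in coords:
        data[c] = True
    return make_volume(data, spacing)


class TestSkeletonize:
    def test_straight_tube_gives_single_centered_path(self, straight_tube_graph):
        res = rasterize_network(straight_tube_graph, (0.5, 0.5, 1.0), domain=(30, 30, 60))
        skel = skeletonize_mask(res.mask)
        vox = np.argwhere(skel.voxels)
        assert len(vox) > 20
        # one voxel per z-slice along the tube interior, all at the same (x, y)
        zs = vox[:, 2]
        assert len(np.unique(zs)) == len(zs)
        assert np.ptp(vox[:, 0]) <= 1 and np.ptp(vox[:, 1]) <= 1

    def test_offset_tube_regression_not_erased(self):
        """Straight tubes at awkward sub-voxel offsets must keep a skeleton.

        (Plain Lee-style thinning in some library versions deletes these
        entirely; homotopic thinning may not.)
        """
        x, y, z = np.meshgrid(np.arange(44), np.arange(44), np.arange(30), indexing="ij")
        m = ((x - 22 - 0.26) ** 2 + (y - 22 - 0.42) ** 2 <= 8.2**2)
        skel = skeletonize_mask(make_volume(m))
        assert skel.voxels.sum() >= 10

    def test_two_disjoint_tubes_two_components(self):
        x, y, z = np.meshgrid(np.arange(40), np.arange(20), np.arange(30), indexing="ij")
        m = ((x - 10) ** 2 + (y - 10) ** 2 <= 9) | ((x - 30) ** 2 + (y - 10) ** 2 <= 9)
        skel = skeletonize_mask(make_volume(m))
        from scipy import ndimage

        _, n = ndimage.label(skel.voxels, structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_torus_skeleton_keeps_exactly_one_cycle(self):
        """Euler characteristic: |V| − |E| = 0 for a single closed curve."""
        x, y, z = np.meshgrid(np.arange(48), np.arange(48), np.arange(16), indexing="ij")
        ring = (np.sqrt((x - 24) ** 2 + (y - 24) ** 2) - 15) ** 2 + (z - 8) ** 2 <= 16
        skel = skeletonize_mask(make_volume(ring))
        graph = build_vessel_graph(skel)
        n_nodes = len(graph.nodes)
        n_edges = len(graph.segments)
        loops = sum(1 for s in graph.segments if s.node_a == s.node_b)
        assert n_edges - n_nodes + graph.n_filaments == 1  # one independent cycle
        assert loops >= 0

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize_mask(make_volume(np.zeros((9, 9, 9), bool)))
        assert not skel.voxels.any()


class TestBuildGraph:
    def test_y_shape_counts(self):
        coords = (
            [(10, 10, k) for k in range(3, 10)]          # stem
            + [(10 + i, 10 + i, 10 + i) for i in range(0, 6)]  # branch A (diagonal)
            + [(10 - i, 10 + i, 10 + i) for i in range(1, 6)]  # branch B
        )
        vol = _skeleton_volume(coords, (20, 20, 20))
        graph = build_vessel_graph(vol)
        degrees = {}
        for s in graph.segments:
            for n in (s.node_a, s.node_b):
                degrees[n] = degrees.get(n, 0) + 1
        assert len(graph.segments) == 3
        assert sorted(degrees.values()) == [1, 1, 1, 3]

    def test_pure_cycle_single_loop_segment(self):
        # diamond ring: every voxel has exactly two 26-neighbours
        R = 6
        coords = []
        for dx in range(-R, R + 1):
            for dy in {R - abs(dx), -(R - abs(dx))}:
                coords.append((10 + dx, 10 + dy, 5))
        coords = list(dict.fromkeys(coords))
        vol = _skeleton_volume(coords, (20, 20, 11))
        graph = build_vessel_graph(vol)
        assert len(graph.segments) == 1
        seg = graph.segments[0]
        assert seg.node_a == seg.node_b
        assert seg.length == pytest.approx(len(coords) * math.sqrt(2.0), abs=1e-9)

    def test_recovers_generated_topology(self, fiber_phantom):
        """Traced segment count within ±10% of the generator's truth."""
        _, graph_gt, gt, raster = fiber_phantom
        traced, table = trace_mask(raster.mask)
        n_true = len(graph_gt.segments)
        assert abs(len(traced.segments) - n_true) <= 0.1 * n_true

    def test_total_length_independent_of_axis_order(self, straight_tube_graph):
        res = rasterize_network(straight_tube_graph, (1.0, 1.0, 1.0), domain=(30, 30, 60))
        skel = skeletonize_mask(res.mask)
        g1 = build_vessel_graph(skel)
        transposed = make_volume(np.transpose(skel.voxels, (2, 1, 0)), (1.0, 1.0, 1.0))
        g2 = build_vessel_graph(transposed)
        assert g1.total_length == pytest.approx(g2.total_length, rel=1e-9)


class TestMeasureSegment:
    def test_straight_segment(self):
        pts = np.array([[0, 0, 0], [0, 0, 5], [0, 0, 10.0]])
        rec = measure_segment(pts, np.array([2.0, 2.0, 2.0]))
        assert rec.length == pytest.approx(10.0)
        assert rec.straightness == pytest.approx(1.0)
        assert rec.mean_diameter == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "arc_fraction,expected",
        [(0.5, 2 / math.pi), (0.25, 2 * math.sqrt(2) / math.pi)],
    )
    def test_circular_arc_straightness_closed_forms(self, arc_fraction, expected):
        """Half/quarter circles: chord/arc = sin(θ)/θ at fine resolution."""
        theta = arc_fraction * 2 * math.pi
        ts = np.linspace(0, theta, 4001)
        pts = np.stack([10 * np.cos(ts), 10 * np.sin(ts), np.zeros_like(ts)], axis=1)
        rec = measure_segment(pts, np.full(len(pts), 1.0), trim_endpoint_radii=False)
        assert abs(rec.straightness - expected) < 1e-3

    def test_loop_flagged_straightness_zero(self):
        ts = np.linspace(0, 2 * math.pi, 100)
        pts = np.stack([np.cos(ts), np.sin(ts), np.zeros_like(ts)], axis=1)
        pts[-1] = pts[0]
        rec = measure_segment(pts, np.full(len(pts), 1.0))
        assert rec.is_loop
        assert rec.straightness == 0.0

    @pytest.mark.parametrize(
        "chord,expected",
        [((1, 0, 0), 0.0), ((1, 1, 0), 45.0), ((0, 1, 0), 90.0),
         ((-1, 1, 0), -45.0), ((-1, 0, 0), 0.0), ((0, -2, 5), 90.0)],
    )
    def test_orientation_axial_range(self, chord, expected):
        pts = np.array([[0.0, 0.0, 0.0], list(map(float, chord))])
        rec = measure_segment(pts, np.array([1.0, 1.0]))
        assert rec.orientation_xy == pytest.approx(expected)
        assert -90 < rec.orientation_xy <= 90

    def test_straightness_one_iff_collinear(self, rng):
        direction = rng.standard_normal(3)
        ts = np.sort(rng.random(30))
        pts = np.outer(ts, direction)
        rec = measure_segment(pts, np.full(30, 1.0))
        assert rec.straightness == pytest.approx(1.0, abs=1e-9)
        bent = pts.copy()
        bent[15] += 0.5
        rec2 = measure_segment(bent, np.full(30, 1.0))
        assert rec2.straightness < 1.0 - 1e-9


class TestBoundaryRemoval:
    def test_face_touching_removed_interior_kept(self):
        import pandas as pd

        table = pd.DataFrame(
            dict(
                segment_id=[0, 1], filament_id=[0, 0],
                length=[10.0, 10.0], mean_diameter=[4.0, 4.0],
                straightness=[1.0, 1.0], orientation_xy=[0.0, 0.0],
                touches_boundary=[False, False], is_loop=[False, False],
                x_start=[0.0, 40.0], y_start=[50.0, 50.0], z_start=[50.0, 50.0],
                x_end=[10.0, 50.0], y_end=[50.0, 50.0], z_end=[50.0, 50.0],
            )
        )
        out = remove_boundary_segments(table, bounds=(100.0, 100.0, 100.0), boundary_tol=1.0)
        assert list(out["segment_id"]) == [1]

    def test_rim_filter_reduces_length_bias(self, fiber_phantom):
        _, _, gt, raster = fiber_phantom
        _, table = trace_mask(raster.mask)
        clean = remove_boundary_segments(table)
        truth = gt.interior_mean_segment_length
        assert abs(clean["length"].mean() - truth) < abs(table["length"].mean() - truth)


class TestOrientationStats:
    def test_identical_angles_map_to_zero(self):
        centered, _, _ = center_orientation_distribution(np.full(50, 37.0))
        assert np.allclose(centered, 0.0)

    def test_uniform_angles_stay_flat(self, rng):
        angles = rng.uniform(-90, 90, 20000)
        _, _, freqs = center_orientation_distribution(angles, bin_width=5.0)
        assert freqs.sum() == pytest.approx(1.0)
        expected = 1 / len(freqs)
        sigma = math.sqrt(expected * (1 - expected) / 20000)
        assert np.all(np.abs(freqs - expected) < 5 * sigma)

    def test_parallel_fibers_more_aligned_than_arcs(self, fiber_phantom, arc_phantom):
        """Muscle-like phantoms have a far tighter orientation spread than
        brain-like ones, measured in the plane containing the fiber axis."""
        _, g_fib, _, _ = fiber_phantom
        _, g_arc, _ = arc_phantom

        def axial_angles(segments, i, j):
            chords = np.array([s.points[-1] - s.points[0] for s in segments])
            a = np.degrees(np.arctan2(chords[:, j], chords[:, i]))
            a = (a + 90.0) % 180.0 - 90.0
            return a

        # the capillaries proper (long z-runs), excluding the sparse cross-links
        fib = [s for s in g_fib.segments if abs(s.points[-1][2] - s.points[0][2]) > 1]
        assert len(fib) > 5
        sd_fib = circular_sd(axial_angles(fib, 0, 2))  # x–z plane holds the fibers
        sd_arc = circular_sd(axial_angles(g_arc.segments, 0, 2))
        assert sd_fib < sd_arc
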