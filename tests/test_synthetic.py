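"""Generator contracts: ground truth, calibration, determinism, rasterization."""

import math

import numpy as np
import pytest

from angioquant.graph import VesselGraph, segment_straightness
from angioquant.synthetic import (
    NetworkSpec,
    NoiseModel,
    generate_network,
    generate_parallel_fiber_network,
    generate_planar_mesh_network,
    generate_random_arc_network,
    generate_tumor_network,
    rasterize_network,
    surface_distance_to_graph,
    volume_fraction_mc,
)


class TestNetworkSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(target_volume_fraction=0.0),
            dict(target_volume_fraction=1.0),
            dict(tortuosity=0.9),
            dict(mean_radius=-1.0),
            dict(domain_size=(0.0, 100.0, 100.0)),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(archetype="random_arc", domain_size=(100.0, 100.0, 100.0))
        base.update(kwargs)
        with pytest.raises(ValueError):
            NetworkSpec(**base)


class TestParallelFiber:
    def test_unjittered_lattice_max_surface_distance_closed_form(self):
        """pitch/√2 − r for the cell-diagonal midpoint, checked brute-force."""
        pitch = 100.409
        spec = NetworkSpec(
            "parallel_fiber", (2 * pitch, 2 * pitch, 30.0),
            mean_radius=5.0, lattice_pitch=pitch, cross_links=False, seed=0,
        )
        graph, gt = generate_parallel_fiber_network(spec)
        expected = pitch / math.sqrt(2.0) - 5.0
        assert gt.analytic_max_surface_distance == pytest.approx(expected, abs=1e-9)
        # brute-force: scan a fine grid of tissue points for the farthest one
        xs = np.linspace(0, 2 * pitch, 81)
        pts = np.array([(x, y, 15.0) for x in xs for y in xs])
        dists = surface_distance_to_graph(pts, graph)
        assert dists.max() == pytest.approx(expected, abs=2.5)

    def test_single_cylinder_volume_fraction_closed_form(self):
        g = VesselGraph()
        a = g.add_node((20.0, 20.0, 0.0))
        b = g.add_node((20.0, 20.0, 50.0))
        g.add_segment(a, b, np.array([[20.0, 20.0, 0.0], [20.0, 20.0, 50.0]]), 4.0)
        vol = 40.0 * 40.0 * 50.0
        expected = math.pi * 16.0 * 50.0 / vol
        assert volume_fraction_mc(g, (40, 40, 50), 400_000, seed=0) == pytest.approx(
            expected, rel=0.02
        )

    def test_calibration_to_muscle_volume_fraction(self, fiber_phantom):
        _, _, gt, _ = fiber_phantom
        assert 0.0382 <= gt.analytic_volume_fraction <= 0.0398

    def test_interior_mean_segment_length_matches_setpoint(self, fiber_phantom):
        _, _, gt, _ = fiber_phantom
        assert gt.interior_mean_segment_length == pytest.approx(68.5, rel=1e-6)

    def test_infeasible_volume_fraction_rejected(self):
        spec = NetworkSpec(
            "parallel_fiber", (50.0, 50.0, 50.0),
            target_volume_fraction=0.9, mean_radius=4.0, seed=0,
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_parallel_fiber_network(spec)

    def test_same_seed_bit_identical(self):
        spec = dict(
            archetype="parallel_fiber", domain_size=(80.0, 80.0, 120.0),
            target_volume_fraction=0.05, mean_radius=4.0, jitter_fraction=0.2, seed=11,
        )
        g1, _ = generate_network(NetworkSpec(**spec))
        g2, _ = generate_network(NetworkSpec(**spec))
        assert len(g1.segments) == len(g2.segments)
        for s1, s2 in zip(g1.segments, g2.segments):
            assert np.array_equal(s1.points, s2.points)
            assert np.array_equal(s1.radii, s2.radii)


class TestRandomArc:
    def test_orientation_distribution_isotropic(self, arc_phantom):
        """No 20°-bin of chord azimuths deviates > 4σ from uniform."""
        _, graph, _ = arc_phantom
        chords = np.array([s.points[-1] - s.points[0] for s in graph.segments])
        az = np.degrees(np.arctan2(chords[:, 1], chords[:, 0])) % 180.0
        n_bins = 9
        counts, _ = np.histogram(az, bins=n_bins, range=(0, 180))
        n = len(az)
        p = 1.0 / n_bins
        sigma = math.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 4 * sigma)

    def test_zero_tortuosity_parameter_gives_straight_segments(self):
        spec = NetworkSpec(
            "random_arc", (100.0, 100.0, 100.0), n_segments=40,
            mean_segment_length=25.0, mean_radius=3.0, tortuosity=1.0, seed=3,
        )
        graph, _ = generate_random_arc_network(spec)
        for seg in graph.segments:
            assert segment_straightness(seg.points) == pytest.approx(1.0, abs=1e-9)

    def test_arc_straightness_matches_tortuosity(self, arc_phantom):
        """Mean chord/arc tracks 1/τ (τ is jittered per segment around the set-point)."""
        _, graph, gt = arc_phantom
        st = [segment_straightness(s.points) for s in graph.segments]
        assert np.mean(st) == pytest.approx(1.0 / 1.15, rel=0.02)

    def test_fixed_tortuosity_exact_when_jitter_off(self):
        spec = NetworkSpec(
            "random_arc", (100.0, 100.0, 100.0), n_segments=30,
            mean_segment_length=25.0, mean_radius=3.0, tortuosity=1.2,
            tortuosity_jitter=0.0, seed=3,
        )
        graph, _ = generate_random_arc_network(spec)
        # polyline discretization of the arc costs < 0.1% of the exact ratio
        for seg in graph.segments:
            assert segment_straightness(seg.points) == pytest.approx(1.0 / 1.2, rel=2e-3)

    def test_mean_length_clt_bound(self, arc_phantom):
        _, graph, _ = arc_phantom
        lengths = np.array([s.length for s in graph.segments])
        n = len(lengths)
        assert n >= 100
        assert abs(lengths.mean() - 30.0) < 3 * lengths.std() / math.sqrt(n) + 30.0 * 0.05

    def test_main_filament_dominates(self, arc_phantom):
        _, graph, _ = arc_phantom
        per_fil = {}
        for s in graph.segments:
            per_fil[s.filament_id] = per_fil.get(s.filament_id, 0.0) + s.length
        assert per_fil[0] / sum(per_fil.values()) >= 0.90


class TestPlanarMesh:
    def test_mesh_layer_wider_than_feeders(self):
        spec = NetworkSpec(
            "planar_mesh", (150.0, 150.0, 100.0),
            mean_segment_length=37.7, mean_radius=4.0, mesh_radius=6.6, seed=2,
        )
        graph, gt = generate_planar_mesh_network(spec)
        ex = gt.extras
        assert ex["feeder_mean_diameter"] is not None
        assert ex["mesh_mean_diameter"] > ex["feeder_mean_diameter"]
        assert gt.analytic_mean_diameter > ex["feeder_mean_diameter"]

    def test_zero_feeders_is_planar(self):
        spec = NetworkSpec(
            "planar_mesh", (150.0, 150.0, 40.0),
            mean_segment_length=37.7, mean_radius=5.0, feeder_fraction=0.0, seed=2,
        )
        graph, gt = generate_planar_mesh_network(spec)
        zs = np.concatenate([s.points[:, 2] for s in graph.segments])
        assert np.ptp(zs) == pytest.approx(0.0, abs=1e-9)

    def test_mesh_lattice_max_surface_distance_closed_form(self):
        spec = NetworkSpec(
            "planar_mesh", (200.0, 200.0, 60.0),
            mean_segment_length=45.0, mean_radius=5.0, mesh_radius=5.0,
            feeder_fraction=0.0, seed=0,
        )
        graph, gt = generate_planar_mesh_network(spec)
        assert gt.analytic_max_surface_distance == pytest.approx(
            45.0 / math.sqrt(2.0) - 5.0, abs=1e-9
        )


class TestTumor:
    def test_voids_are_vessel_free_and_set_distance_floor(self):
        void = ((100.0, 100.0, 100.0), 60.0)
        spec = NetworkSpec(
            "tumor", (200.0, 200.0, 200.0), n_segments=150,
            mean_segment_length=30.0, mean_radius=3.0, tortuosity=1.2,
            void_spec=[void], dilated_fraction=0.1, seed=4,
        )
        graph, gt = generate_tumor_network(spec)
        for seg in graph.segments:
            d = np.linalg.norm(seg.points - np.array(void[0]), axis=1)
            assert np.all(d >= void[1])
        center_clearance = surface_distance_to_graph(np.array([void[0]]), graph)[0]
        assert center_clearance >= void[1] - 1e-9

    def test_total_void_coverage_rejected(self):
        spec = NetworkSpec(
            "tumor", (100.0, 100.0, 100.0),
            void_spec=[((50.0, 50.0, 50.0), 200.0)], seed=0,
        )
        with pytest.raises(ValueError):
            generate_tumor_network(spec)

    def test_dilation_off_matches_random_arc_generator(self):
        common = dict(
            domain_size=(200.0, 200.0, 200.0), n_segments=120,
            mean_segment_length=30.0, mean_radius=3.0, tortuosity=1.0,
            radius_cv=0.2, seed=9,
        )
        g_t, gt_t = generate_tumor_network(
            NetworkSpec("tumor", dilated_fraction=0.0, n_clusters=1, **common)
        )
        g_a, gt_a = generate_random_arc_network(
            NetworkSpec("random_arc", isolated_length_fraction=0.0, **common)
        )
        # same sampling law: means and CVs agree statistically
        assert gt_t.analytic_mean_diameter == pytest.approx(
            gt_a.analytic_mean_diameter, rel=0.1
        )
        assert gt_t.extras["diameter_cv"] == pytest.approx(
            gt_a.extras["diameter_cv"], abs=0.08
        )

    def test_diameter_cv_bookkeeping_matches_brute_force(self):
        spec = NetworkSpec(
            "tumor", (200.0, 200.0, 200.0), n_segments=150,
            mean_segment_length=30.0, mean_radius=3.0,
            dilated_fraction=0.1, dilation_factor=3.0, seed=5,
        )
        graph, gt = generate_tumor_network(spec)
        diams = np.array([2.0 * s.mean_radius for s in graph.segments])
        assert gt.extras["diameter_cv"] == pytest.approx(
            float(diams.std() / diams.mean()), rel=1e-9
        )
        dilated = gt.extras["dilated_segment_ids"]
        assert len(dilated) >= 1
        for sid in dilated:
            assert graph.segments[sid].mean_radius >= 2.0 * 3.0  # ≥ 2× mean radius

    def test_tumor_diameter_cv_exceeds_organ_archetype(self):
        common = dict(
            domain_size=(200.0, 200.0, 200.0), n_segments=120,
            mean_segment_length=30.0, mean_radius=3.0, seed=6,
        )
        _, gt_t = generate_tumor_network(
            NetworkSpec("tumor", tortuosity=1.3, radius_cv=0.3, dilated_fraction=0.1, **common)
        )
        _, gt_a = generate_random_arc_network(
            NetworkSpec("random_arc", tortuosity=1.05, radius_cv=0.0, **common)
        )
        assert gt_t.extras["diameter_cv"] > gt_a.extras["diameter_cv"]


class TestGroundTruthConsistency:
    def test_analytic_values_recomputable_from_graph(self, fiber_phantom):
        _, graph, gt, _ = fiber_phantom
        lengths = [s.length for s in graph.segments]
        diams = [2 * s.mean_radius for s in graph.segments]
        assert gt.analytic_mean_segment_length == pytest.approx(np.mean(lengths), rel=1e-9)
        assert gt.analytic_mean_diameter == pytest.approx(np.mean(diams), rel=1e-9)
        graph.validate()

    def test_voids_increase_ground_truth_max_distance(self):
        # baseline must be space-filling for the exclusion sphere to be the
        # only large-scale gap; a clustered tumor baseline already carries
        # gaps of its own
        common = dict(
            domain_size=(250.0, 250.0, 250.0), target_volume_fraction=0.03,
            mean_segment_length=30.0, mean_radius=3.0, tortuosity=1.2, seed=8,
        )
        g_plain, _ = generate_random_arc_network(NetworkSpec("random_arc", **common))
        g_void, _ = generate_random_arc_network(
            NetworkSpec(
                "random_arc", void_spec=[((125.0, 125.0, 125.0), 80.0)], **common
            )
        )
        grid = np.linspace(15, 235, 12)
        pts = np.array([(x, y, z) for x in grid for y in grid for z in grid])
        pts = np.vstack([pts, [(125.0, 125.0, 125.0)]])
        assert surface_distance_to_graph(pts, g_void).max() > surface_distance_to_graph(
            pts, g_plain
        ).max()


class TestRasterization:
    def test_cylinder_volume_within_5pct(self, straight_tube_graph):
        res = rasterize_network(straight_tube_graph, (0.5, 0.5, 0.5), domain=(30, 30, 60))
        voxel_vol = 0.125
        measured = res.mask.voxels.sum() * voxel_vol
        # capsule = cylinder + two hemispherical end caps
        expected = math.pi * 9.0 * 60.0 + 4.0 / 3.0 * math.pi * 27.0
        # caps protrude beyond the z-faces and are clipped: subtract them back
        expected_clipped = math.pi * 9.0 * 60.0
        assert abs(measured - expected_clipped) / expected_clipped < 0.05

    def test_empty_graph_gives_background(self):
        res = rasterize_network(VesselGraph(), (1.0, 1.0, 1.0), shape=(16, 16, 16))
        assert not res.mask.voxels.any()
        assert not res.intensity.voxels.any()

    def test_noise_free_rasterization_deterministic(self, straight_tube_graph):
        r1 = rasterize_network(straight_tube_graph, (1.0, 1.0, 1.0), domain=(30, 30, 60))
        r2 = rasterize_network(straight_tube_graph, (1.0, 1.0, 1.0), domain=(30, 30, 60))
        assert np.array_equal(r1.mask.voxels, r2.mask.voxels)
        assert np.array_equal(r1.intensity.voxels, r2.intensity.voxels)

    def test_volume_fraction_converges_with_refinement(self):
        """Rasterized volume approaches the analytic capsule volume as the
        grid is refined (oblique axis, so no lattice resonance)."""
        a = np.array([6.3, 7.1, 5.2])
        b = np.array([23.7, 21.9, 52.8])
        r = 3.0
        length = float(np.linalg.norm(b - a))
        analytic = math.pi * r * r * length + 4.0 / 3.0 * math.pi * r**3
        g = VesselGraph()
        na, nb = g.add_node(a), g.add_node(b)
        g.add_segment(na, nb, np.stack([a, b]), r)
        errors = []
        for h in (1.0, 0.5, 0.25):
            res = rasterize_network(g, (h, h, h), domain=(30, 30, 60))
            vol = res.mask.voxels.sum() * h**3
            errors.append(abs(vol - analytic) / analytic)
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 0.005

    def test_noise_model_degrades_intensity_not_mask(self, straight_tube_graph):
        nm = NoiseModel(psf_sigma=0.8, leakiness=0.1, poisson=True, seed=3)
        res = rasterize_network(
            straight_tube_graph, (1.0, 1.0, 1.0), domain=(30, 30, 60), noise_model=nm
        )
        clean = rasterize_network(straight_tube_graph, (1.0, 1.0, 1.0), domain=(30, 30, 60))
        assert np.array_equal(res.mask.voxels, clean.mask.voxels)
        assert res.intensity.voxels.astype(int).max() > 100
        assert len(np.unique(res.intensity.voxels)) > 2
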