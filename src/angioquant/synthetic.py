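"""Synthetic vascular networks with exact ground truth.

Real light-sheet volumes of labelled vasculature are rarely shareable, so
this module generates stand-in networks whose geometry is known exactly and
rasterizes them into image stacks.  Four archetypes cover the qualitative
range seen across healthy organs and tumors:

``parallel_fiber``
    Long straight capillaries on a (optionally jittered) lattice, aligned
    with one axis and connected by sparse cross-links — skeletal-muscle-like.
``random_arc``
    A space-filling connected tree of short curved segments with isotropic
    orientations — brain-cortex-like.
``planar_mesh``
    A single wide-diameter 2D mesh layer fed by parallel perpendicular
    vessels — colon-mucosa-like.
``tumor``
    Heterogeneous clustered growth with avascular void spheres, a fraction
    of short dilated segments, and high tortuosity.

Every generator returns the :class:`~angioquant.graph.VesselGraph` together
with a :class:`GroundTruth` record whose values are reproducible from the
graph geometry alone, so downstream recovery (segmentation → tracing →
statistics) can be validated against truth rather than against itself.

Tubes are capsules (cylinders with hemispherical caps) per polyline edge,
with union semantics at junctions; this keeps volumes and surface distances
well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize

from .graph import VesselGraph, VesselSegment
from .volume import RasterVolume

__all__ = [
    "NetworkSpec",
    "GroundTruth",
    "NoiseModel",
    "RasterizationResult",
    "generate_network",
    "generate_parallel_fiber_network",
    "generate_random_arc_network",
    "generate_planar_mesh_network",
    "generate_tumor_network",
    "rasterize_network",
    "volume_fraction_mc",
    "surface_distance_to_graph",
]

Archetype = Literal["parallel_fiber", "random_arc", "planar_mesh", "tumor"]


# ---------------------------------------------------------------------------
# specs and results
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Parameters of a synthetic network.

    All lengths in µm.  ``target_volume_fraction`` (vessel volume / domain
    volume) is optional; when given, the generator calibrates itself to it.
    ``tortuosity`` is arc length over chord length (≥ 1).  ``void_spec``
    lists hard avascular exclusion spheres as ``(center_xyz, radius)``.
    """

    archetype: Archetype
    domain_size: tuple[float, float, float]
    target_volume_fraction: float | None = None
    mean_segment_length: float = 60.0
    mean_radius: float = 4.0
    radius_cv: float = 0.0
    tortuosity: float = 1.0
    void_spec: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    seed: int = 0
    # archetype-specific knobs
    jitter_fraction: float = 0.0          # parallel_fiber lattice jitter, × pitch
    cross_links: bool = True              # parallel_fiber cross connections
    cross_link_radius_factor: float = 0.8
    lattice_pitch: float | None = None    # parallel_fiber: override calibration
    mesh_radius: float | None = None      # planar_mesh: mesh-layer radius
    feeder_fraction: float = 1.0          # planar_mesh: fraction of nodes with feeders
    n_segments: int | None = None         # random_arc/tumor: override calibration
    tortuosity_jitter: float = 0.3        # random_arc/tumor: relative spread of excess tortuosity
    isolated_length_fraction: float = 0.08  # random_arc: mass outside main filament
    dilated_fraction: float = 0.0         # tumor: fraction of short segments dilated
    dilation_factor: float = 3.0          # tumor: radius multiplier, ≥ 2 is "dilated"
    n_clusters: int = 4                   # tumor: density hot-spots

    def __post_init__(self) -> None:
        if self.archetype not in ("parallel_fiber", "random_arc", "planar_mesh", "tumor"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if any(e <= 0 for e in self.domain_size):
            raise ValueError("domain extents must be positive")
        if self.target_volume_fraction is not None and not (
            0 < self.target_volume_fraction < 1
        ):
            raise ValueError("target_volume_fraction must lie in (0, 1)")
        if self.tortuosity < 1:
            raise ValueError("tortuosity (arc/chord) must be >= 1")
        if self.mean_radius <= 0 or self.mean_segment_length <= 0:
            raise ValueError("mean_radius and mean_segment_length must be positive")


@dataclass
class GroundTruth:
    """Analytic bookkeeping emitted with every generated network.

    ``analytic_volume_fraction`` is exact (closed form) for disjoint-tube
    constructions and a fixed-seed Monte-Carlo union estimate otherwise.
    ``interior_mean_segment_length`` averages only segments that do not touch
    the domain boundary — the quantity a rim-filtered tracing should recover.
    ``analytic_max_surface_distance`` is a closed-form value where the
    construction admits one (unjittered lattices), else ``None``.
    """

    graph: VesselGraph
    analytic_volume_fraction: float
    analytic_mean_segment_length: float
    analytic_mean_diameter: float
    analytic_max_surface_distance: float | None = None
    interior_mean_segment_length: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class NoiseModel:
    """Imaging degradations applied to the intensity channel only.

    ``psf_sigma`` is the Gaussian blur sigma in µm (isotropic), ``leakiness``
    perturbs per-edge radii (fractional sigma) to imitate the uneven, leaky
    vessel surfaces of tumor stacks.  The binary ground-truth mask is never
    degraded.
    """

    psf_sigma: float = 0.0
    background: float = 10.0
    foreground: float = 200.0
    poisson: bool = True
    leakiness: float = 0.0
    seed: int = 0


@dataclass
class RasterizationResult:
    intensity: RasterVolume
    mask: RasterVolume


# ---------------------------------------------------------------------------
# capsule geometry
# ---------------------------------------------------------------------------


def _edge_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                   ra: float, rb: float) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points (N,3) to segment a-b and the local tube radius.

    The radius is linearly interpolated along the edge and evaluated at the
    clamped foot point, i.e. the tube is a tapered capsule.
    """
    d = b - a
    dd = float(d @ d)
    if dd == 0:
        t = np.zeros(len(points))
    else:
        t = np.clip((points - a) @ d / dd, 0.0, 1.0)
    closest = a + t[:, None] * d
    dist = np.linalg.norm(points - closest, axis=1)
    radius = ra + (rb - ra) * t
    return dist, radius


def _segment_clearance(points: np.ndarray, seg: VesselSegment) -> np.ndarray:
    """Signed distance from points to the segment's tube surface (<0 inside)."""
    best = np.full(len(points), np.inf)
    pts, radii = seg.points, seg.radii
    for i in range(len(pts) - 1):
        dist, rad = _edge_distance(points, pts[i], pts[i + 1], radii[i], radii[i + 1])
        np.minimum(best, dist - rad, out=best)
    return best


def surface_distance_to_graph(points: np.ndarray, graph: VesselGraph) -> np.ndarray:
    """Brute-force distance from arbitrary points to the nearest tube surface.

    Negative values mean the point lies inside a vessel.  O(points × edges);
    intended as an oracle on small inputs, not a production distance map.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    best = np.full(len(points), np.inf)
    for seg in graph.segments:
        np.minimum(best, _segment_clearance(points, seg), out=best)
    return best


def volume_fraction_mc(
    graph: VesselGraph,
    domain: Sequence[float],
    n_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo vessel volume fraction of the capsule union in a box.

    Samples voxel-free uniform points in ``[0, X]×[0, Y]×[0, Z]`` and tests
    capsule membership, so overlaps at junctions are counted once (union
    semantics).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    domain = np.asarray(domain, dtype=float)
    pts = rng.random((n_samples, 3)) * domain
    outside = np.ones(n_samples, dtype=bool)
    for seg in graph.segments:
        idx = np.flatnonzero(outside)
        if idx.size == 0:
            break
        # bounding-box prefilter before the exact capsule test
        rmax = float(seg.radii.max())
        lo = seg.points.min(axis=0) - rmax
        hi = seg.points.max(axis=0) + rmax
        cand = idx[np.all((pts[idx] >= lo) & (pts[idx] <= hi), axis=1)]
        if cand.size == 0:
            continue
        inside = _segment_clearance(pts[cand], seg) <= 0
        outside[cand[inside]] = False
    return float(1.0 - outside.mean())


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_network(
    graph: VesselGraph,
    spacing: Sequence[float],
    noise_model: NoiseModel | None = None,
    shape: Sequence[int] | None = None,
    domain: Sequence[float] | None = None,
) -> RasterizationResult:
    """Rasterize a vessel network into an image stack plus ground-truth mask.

    A voxel is foreground iff its center lies inside the union of segment
    tubes (capsules per polyline edge).  ``shape`` fixes the grid directly;
    otherwise it is derived from ``domain`` (or the graph bounding box) as
    ``round(extent / spacing)``.  Voxel centers sit at ``index * spacing``.

    With a :class:`NoiseModel`, the intensity copy gets optional surface
    perturbation ("leakiness"), Gaussian blur, a background pedestal and
    Poisson noise; the returned mask is always the clean binary truth.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if shape is None:
        if domain is None:
            _, hi = graph.bounding_box()
            rmax = max((float(s.radii.max()) for s in graph.segments), default=1.0)
            domain = hi + rmax
        shape = tuple(int(round(e / s)) for e, s in zip(domain, spacing))
    shape = tuple(int(n) for n in shape)
    if any(n < 1 for n in shape):
        raise ValueError("derived grid shape is empty")
    if math.prod(shape) > 600_000_000:
        raise ValueError(f"grid {shape} exceeds the addressable limit")

    mask = np.zeros(shape, dtype=bool)
    _paint_graph(mask, graph, spacing)

    mask_vol = RasterVolume(mask, tuple(spacing), check_shape=False)
    if noise_model is None:
        intensity = RasterVolume(
            (mask * np.uint8(255)).astype(np.uint8), tuple(spacing), check_shape=False
        )
        return RasterizationResult(intensity, mask_vol)

    nm = noise_model
    rng = np.random.default_rng(nm.seed)
    if nm.leakiness > 0:
        leaky = _perturb_radii(graph, nm.leakiness, rng)
        raw = np.zeros(shape, dtype=bool)
        _paint_graph(raw, leaky, spacing)
    else:
        raw = mask
    img = np.where(raw, nm.foreground, nm.background).astype(np.float32)
    if nm.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=nm.psf_sigma / spacing)
    if nm.poisson:
        img = rng.poisson(img).astype(np.float32)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return RasterizationResult(RasterVolume(img, tuple(spacing), check_shape=False), mask_vol)


def _paint_graph(mask: np.ndarray, graph: VesselGraph, spacing: np.ndarray) -> None:
    shape = mask.shape
    for seg in graph.segments:
        pts, radii = seg.points, seg.radii
        for i in range(len(pts) - 1):
            a, b = pts[i], pts[i + 1]
            rmax = max(radii[i], radii[i + 1])
            lo_idx = np.maximum(
                np.floor((np.minimum(a, b) - rmax) / spacing).astype(int) - 1, 0
            )
            hi_idx = np.minimum(
                np.ceil((np.maximum(a, b) + rmax) / spacing).astype(int) + 2,
                np.asarray(shape),
            )
            if np.any(lo_idx >= hi_idx):
                continue
            xs = (np.arange(lo_idx[0], hi_idx[0]) * spacing[0])[:, None, None]
            ys = (np.arange(lo_idx[1], hi_idx[1]) * spacing[1])[None, :, None]
            zs = (np.arange(lo_idx[2], hi_idx[2]) * spacing[2])[None, None, :]
            d = b - a
            dd = float(d @ d)
            px, py, pz = xs - a[0], ys - a[1], zs - a[2]
            if dd == 0:
                t = np.zeros(1)[:, None, None]
            else:
                t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / dd, 0.0, 1.0)
            cx, cy, cz = px - t * d[0], py - t * d[1], pz - t * d[2]
            dist2 = cx * cx + cy * cy + cz * cz
            rad = radii[i] + (radii[i + 1] - radii[i]) * t
            sub = dist2 <= rad * rad
            mask[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] |= sub


def _perturb_radii(graph: VesselGraph, leakiness: float, rng: np.random.Generator) -> VesselGraph:
    out = VesselGraph(nodes=dict(graph.nodes))
    for seg in graph.segments:
        factors = np.clip(1.0 + leakiness * rng.standard_normal(len(seg.radii)), 0.3, 3.0)
        out.add_segment(seg.node_a, seg.node_b, seg.points.copy(), seg.radii * factors)
    return out


# ---------------------------------------------------------------------------
# ground-truth bookkeeping
# ---------------------------------------------------------------------------


def _boundary_touching(seg: VesselSegment, domain: Sequence[float], tol: float = 1.0) -> bool:
    for pt in (seg.points[0], seg.points[-1]):
        if np.any(pt <= tol) or np.any(np.asarray(domain) - pt <= tol):
            return True
    return False


def _make_ground_truth(
    graph: VesselGraph,
    spec: NetworkSpec,
    volume_fraction: float,
    max_surface_distance: float | None = None,
    extras: dict | None = None,
) -> GroundTruth:
    lengths = np.array([s.length for s in graph.segments])
    diams = np.array([2.0 * s.mean_radius for s in graph.segments])
    interior = np.array(
        [not _boundary_touching(s, spec.domain_size) for s in graph.segments], dtype=bool
    )
    return GroundTruth(
        graph=graph,
        analytic_volume_fraction=volume_fraction,
        analytic_mean_segment_length=float(lengths.mean()) if lengths.size else 0.0,
        analytic_mean_diameter=float(diams.mean()) if diams.size else 0.0,
        analytic_max_surface_distance=max_surface_distance,
        interior_mean_segment_length=(
            float(lengths[interior].mean()) if interior.any() else None
        ),
        extras=dict(
            diameter_cv=float(diams.std() / diams.mean()) if diams.size else 0.0,
            interior_mask=interior,
            **(extras or {}),
        ),
    )


def _sample_radius(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1 + cv**2)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# parallel fibers (muscle archetype)
# ---------------------------------------------------------------------------


def generate_parallel_fiber_network(spec: NetworkSpec) -> tuple[VesselGraph, GroundTruth]:
    """Long straight z-aligned capillaries on a lattice with cross-links.

    The lattice pitch comes from ``target_volume_fraction`` via the continuum
    relation ``vf = πr²/pitch²`` (or from ``lattice_pitch``); because the
    fiber count is integer, radii are then trimmed by a few bounded
    Monte-Carlo iterations so the union volume fraction lands within 2%
    relative of the target.  Cross-link plane spacing is solved so that the
    mean length of *interior* segments matches ``mean_segment_length``.

    For an unjittered lattice without cross-links, the maximal distance from
    tissue to a vessel surface has the closed form ``pitch/√2 − r``, recorded
    in the ground truth.
    """
    if spec.archetype != "parallel_fiber":
        raise ValueError("spec.archetype must be 'parallel_fiber'")
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.domain_size
    r = spec.mean_radius

    if spec.lattice_pitch is not None:
        pitch = float(spec.lattice_pitch)
    elif spec.target_volume_fraction is not None:
        pitch = r * math.sqrt(math.pi / spec.target_volume_fraction)
    else:
        pitch = 4 * spec.mean_radius
    if pitch <= 2.2 * r:
        raise ValueError(
            f"target volume fraction infeasible: lattice pitch {pitch:.2f} µm "
            f"would make radius-{r} µm fibers touch"
        )
    nx_f = max(1, int(round(X / pitch)))
    ny_f = max(1, int(round(Y / pitch)))
    margin = r + 1.0
    xs = (np.arange(nx_f) + 0.5) * (X / nx_f)
    ys = (np.arange(ny_f) + 0.5) * (Y / ny_f)
    centers = np.array([(x, y) for x in xs for y in ys])
    if spec.jitter_fraction > 0:
        centers = centers + rng.uniform(
            -spec.jitter_fraction * pitch, spec.jitter_fraction * pitch, centers.shape
        )
        centers[:, 0] = np.clip(centers[:, 0], margin, X - margin)
        centers[:, 1] = np.clip(centers[:, 1], margin, Y - margin)

    graph = VesselGraph()
    n_fibers = len(centers)

    if spec.cross_links and n_fibers >= 2:
        pairs = _adjacent_pairs(nx_f, ny_f)
        plane_zs, dz = _solve_cross_link_planes(
            Z, spec.mean_segment_length, len({i for p in pairs for i in p}),
            pairs, centers, z_margin=r + 4.0,
        )
    else:
        pairs, plane_zs, dz = [], [], None

    # fibers, cut only where a cross-link attaches (so the emitted topology
    # is exactly what a tracing of the rasterized network can recover)
    linked = {i for p in pairs for i in p}
    for fi, (fx, fy) in enumerate(centers):
        zs = [0.0, *(plane_zs if fi in linked else []), Z]
        node_ids = [graph.add_node((fx, fy, z)) for z in zs]
        for a, b, za, zb in zip(node_ids[:-1], node_ids[1:], zs[:-1], zs[1:]):
            pts = np.array([[fx, fy, za], [fx, fy, zb]])
            graph.add_segment(a, b, pts, r)

    # cross-links between adjacent fibers at each plane
    node_lookup = {
        (round(p[0], 6), round(p[1], 6), round(p[2], 6)): nid
        for nid, p in graph.nodes.items()
    }
    rc = spec.cross_link_radius_factor * r
    for z in plane_zs:
        for i, j in pairs:
            a = node_lookup[(round(centers[i][0], 6), round(centers[i][1], 6), round(z, 6))]
            b = node_lookup[(round(centers[j][0], 6), round(centers[j][1], 6), round(z, 6))]
            pts = np.array([[*centers[i], z], [*centers[j], z]])
            graph.add_segment(a, b, pts, rc)

    # calibrate to the target volume fraction by bounded radius trimming
    if spec.target_volume_fraction is not None:
        vf = _trim_radii_to_vf(
            graph, spec.domain_size, spec.target_volume_fraction, seed=spec.seed
        )
    else:
        vf = volume_fraction_mc(graph, spec.domain_size, seed=spec.seed)

    max_sd = None
    if spec.jitter_fraction == 0 and not spec.cross_links and nx_f > 1 and ny_f > 1:
        eff_r = graph.segments[0].radii[0]
        max_sd = (X / nx_f) / math.sqrt(2.0) - float(eff_r)

    graph.assign_filaments()
    gt = _make_ground_truth(
        graph, spec, vf, max_sd,
        extras=dict(lattice_pitch=pitch, n_fibers=n_fibers, cross_link_plane_spacing=dz),
    )
    return graph, gt


def _adjacent_pairs(nx_f: int, ny_f: int) -> list[tuple[int, int]]:
    """Pair lattice-adjacent fibers (cross-links must not cross other fibers).

    Fiber index = ix * ny_f + iy.  Columns are paired along x two by two;
    a leftover odd column is paired internally along y.
    """
    pairs: list[tuple[int, int]] = []
    for ix in range(0, nx_f - 1, 2):
        for iy in range(ny_f):
            pairs.append((ix * ny_f + iy, (ix + 1) * ny_f + iy))
    if nx_f % 2 == 1 and nx_f >= 1:
        ix = nx_f - 1
        for iy in range(0, ny_f - 1, 2):
            pairs.append((ix * ny_f + iy, ix * ny_f + iy + 1))
    return pairs


def _solve_cross_link_planes(
    Z: float,
    target_mean: float,
    n_linked_fibers: int,
    pairs: list[tuple[int, int]],
    centers: np.ndarray,
    z_margin: float = 6.0,
) -> tuple[list[float], float | None]:
    """Choose cross-link plane spacing so interior segments average target_mean.

    Interior segments are the fiber pieces between consecutive planes (the
    end pieces touch the z-faces and are rim-filtered away) plus the
    cross-links themselves.  For K planes at spacing dz:
    mean = (F(K−1)dz + K·Σ|pair|) / (F(K−1) + K·n_pairs).  The plane stack
    is centered in z so every plane keeps ``z_margin`` from the faces; the
    largest feasible K is used (most segments).  If no K fits, planes fall
    back to even spacing at roughly target_mean intervals.
    """
    pair_len = sum(
        float(np.linalg.norm(centers[i] - centers[j])) for i, j in pairs
    )
    n_pairs = len(pairs)
    for K in range(min(60, int(Z / 4)), 1, -1):
        n_int = n_linked_fibers * (K - 1)
        if n_int == 0:
            continue
        dz = (target_mean * (n_int + K * n_pairs) - K * pair_len) / n_int
        if dz <= 2.0:
            continue
        span = (K - 1) * dz
        if span <= Z - 2 * z_margin:
            z0 = (Z - span) / 2.0
            return [z0 + k * dz for k in range(K)], dz
    K = max(1, int(round(Z / target_mean)) - 1)
    dz = Z / (K + 1)
    return [k * dz for k in range(1, K + 1)], dz


def _trim_radii_to_vf(
    graph: VesselGraph,
    domain: Sequence[float],
    target: float,
    seed: int,
    n_samples: int = 200_000,
    max_iter: int = 4,
    max_total_scale: float = 1.6,
) -> float:
    """Scale all radii (bounded) until the MC union volume fraction hits target."""
    total = 1.0
    vf = volume_fraction_mc(graph, domain, n_samples, seed=seed + 101)
    for it in range(max_iter):
        if vf <= 0:
            raise ValueError("network has zero volume; cannot calibrate")
        scale = math.sqrt(target / vf)
        total *= scale
        if not (1 / max_total_scale <= total <= max_total_scale):
            raise ValueError(
                f"target volume fraction {target} infeasible for this geometry "
                f"(required radius scale {total:.2f})"
            )
        for seg in graph.segments:
            seg.radii = seg.radii * scale
        vf = volume_fraction_mc(graph, domain, n_samples, seed=seed + 202 + it)
        if abs(vf - target) / target < 0.01:
            break
    return vf


# ---------------------------------------------------------------------------
# random arcs (brain archetype)
# ---------------------------------------------------------------------------


def _arc_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    arc_length: float,
    tortuosity: float,
    normal_hint: np.ndarray,
    n_points: int = 17,
) -> np.ndarray:
    """Circular arc of given arc length whose arc/chord ratio is `tortuosity`."""
    u = direction / np.linalg.norm(direction)
    if tortuosity <= 1.0 + 1e-12:
        ts = np.linspace(0.0, arc_length, n_points)
        return start + ts[:, None] * u
    # solve sinθ/θ = 1/τ for the half-angle θ
    theta = optimize.brentq(
        lambda th: math.sin(th) / th - 1.0 / tortuosity, 1e-9, math.pi - 1e-9
    )
    R = arc_length / (2 * theta)
    w = normal_hint - (normal_hint @ u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        w = np.array([u[1], -u[0], 0.0])
        nw = np.linalg.norm(w)
    w = w / nw
    phis = np.linspace(-theta, theta, n_points)
    center = start + R * math.sin(theta) * u - R * math.cos(theta) * w
    pts = center[None] + R * np.sin(phis)[:, None] * u + R * np.cos(phis)[:, None] * w
    return pts


def _point_clear_of_voids(pts: np.ndarray, voids, radius: float) -> bool:
    for center, vr in voids:
        d = np.linalg.norm(pts - np.asarray(center, dtype=float), axis=1)
        if np.any(d < vr + radius):
            return False
    return True


def generate_random_arc_network(spec: NetworkSpec) -> tuple[VesselGraph, GroundTruth]:
    """Space-filling tree of short curved segments with isotropic orientation.

    Segments grow from randomly chosen existing nodes in directions drawn
    uniformly on the sphere; arc length is the spec mean (±30% lognormal
    spread), curvature follows ``tortuosity``.  One main filament carries
    ≥ 90% of the total centerline length; a small isolated fraction of short
    filaments mimics vessels whose connections leave the field of view.
    """
    if spec.archetype not in ("random_arc", "tumor"):
        raise ValueError("spec.archetype must be 'random_arc'")
    return _grow_arcs(spec, clustered=False)


def _grow_arcs(spec: NetworkSpec, clustered: bool) -> tuple[VesselGraph, GroundTruth]:
    X, Y, Z = spec.domain_size
    domain = np.asarray(spec.domain_size)
    r_mean, L = spec.mean_radius, spec.mean_segment_length
    margin = 2.0 * r_mean + 1.0

    if spec.n_segments is not None:
        n_target = spec.n_segments
    elif spec.target_volume_fraction is not None:
        vol = X * Y * Z
        n_target = max(
            8, int(round(spec.target_volume_fraction * vol / (math.pi * r_mean**2 * L)))
        )
    else:
        n_target = 300

    def build(n_tot: int) -> tuple[VesselGraph, list[int]]:
        """Grow a network of ~n_tot segments; fully determined by spec.seed."""
        rng = np.random.default_rng(spec.seed)
        if clustered:
            cluster_centers = margin + rng.random((max(1, spec.n_clusters), 3)) * (
                domain - 2 * margin
            )
            cluster_weights = rng.dirichlet(np.full(len(cluster_centers), 0.6))
            cluster_sd = float(domain.min()) / 6.0
        else:
            cluster_centers = None
        graph = VesselGraph()
        iso_budget = 0
        if not clustered and spec.isolated_length_fraction > 0:
            iso_budget = max(1, int(spec.isolated_length_fraction * n_tot))

        def sample_start() -> np.ndarray | None:
            for _ in range(200):
                p = margin + rng.random(3) * (domain - 2 * margin)
                if _point_clear_of_voids(p[None], spec.void_spec, r_mean):
                    return p
            return None

        def sample_target() -> np.ndarray:
            if cluster_centers is None or rng.random() < 0.2:
                return margin + rng.random(3) * (domain - 2 * margin)
            # heterogeneous coverage: aim at Dirichlet-weighted hot-spots
            k = int(rng.choice(len(cluster_centers), p=cluster_weights))
            t = cluster_centers[k] + cluster_sd * rng.standard_normal(3)
            return np.clip(t, margin, domain - margin)

        def grow_component(n_segs: int, start: np.ndarray) -> int:
            """Space-filling expansion: grow from the node nearest a sampled
            target toward it (rapidly-exploring random tree), capping node
            degree at 3 so junctions stay anatomical bifurcations."""
            root = graph.add_node(start)
            positions = [graph.nodes[root]]
            node_ids = [root]
            degree = {root: 0}
            made = 0
            tries = 0
            while made < n_segs and tries < 150 * n_segs:
                tries += 1
                target = sample_target()
                d2 = np.sum((np.asarray(positions) - target) ** 2, axis=1)
                order = np.argsort(d2)
                nid = None
                for cand in order[:6]:
                    if degree[node_ids[cand]] < 3:
                        nid = node_ids[cand]
                        break
                if nid is None:
                    continue
                u = target - graph.nodes[nid]
                nu = np.linalg.norm(u)
                if nu < 1e-9:
                    continue
                u = u / nu
                arc_len = float(
                    L * rng.lognormal(-0.5 * math.log(1.09), math.sqrt(math.log(1.09)))
                )
                normal_hint = rng.standard_normal(3)
                tau = spec.tortuosity
                if spec.tortuosity_jitter > 0 and tau > 1.0:
                    j = spec.tortuosity_jitter
                    tau = 1.0 + (tau - 1.0) * float(
                        rng.lognormal(-0.5 * math.log(1 + j**2), math.sqrt(math.log(1 + j**2)))
                    )
                pts = _arc_polyline(graph.nodes[nid], u, arc_len, tau, normal_hint)
                radius = _sample_radius(rng, r_mean, spec.radius_cv)
                if np.any(pts < margin) or np.any(pts > domain - margin):
                    continue
                if not _point_clear_of_voids(pts, spec.void_spec, radius):
                    continue
                new = graph.add_node(pts[-1])
                graph.add_segment(nid, new, pts, radius)
                degree[nid] += 1
                degree[new] = 1
                positions.append(graph.nodes[new])
                node_ids.append(new)
                made += 1
            return made

        start = sample_start()
        if start is None:
            raise ValueError("void spheres cover the usable domain; nothing can grow")
        grow_component(n_tot - iso_budget, start)
        for _ in range(iso_budget):
            s = sample_start()
            if s is not None:
                grow_component(1, s)
        if len(graph.segments) == 0:
            raise ValueError("no segments could be placed (domain too constrained)")

        # tumor-specific: dilate a fraction of the short segments (skipping
        # candidates whose dilated tube would bulge into a void sphere)
        dilated: list[int] = []
        if clustered and spec.dilated_fraction > 0:
            lengths = np.array([s.length for s in graph.segments])
            short = np.argsort(lengths)[: max(1, len(lengths) // 2)]
            n_dil = max(1, int(round(spec.dilated_fraction * len(graph.segments))))
            for sid in rng.permutation(short):
                if len(dilated) >= n_dil:
                    break
                seg = graph.segments[int(sid)]
                new_r = float(seg.radii.max()) * spec.dilation_factor
                if not _point_clear_of_voids(seg.points, spec.void_spec, new_r):
                    continue
                seg.radii = seg.radii * spec.dilation_factor
                dilated.append(int(sid))
        return graph, dilated

    # segment-count calibration: junction overlap and clustering make the
    # continuum count estimate run low/high, so re-grow with a scaled count
    # until the Monte-Carlo union volume lands near the target
    n_try = n_target
    graph, dilated_ids = build(n_try)
    if spec.target_volume_fraction is not None and spec.n_segments is None:
        # the union volume is a noisy function of the segment count (every
        # regrowth reshuffles overlaps), so track the best build seen and
        # damp the count updates rather than trusting any single estimate
        target = spec.target_volume_fraction
        best = None
        for _ in range(6):
            vf_est = volume_fraction_mc(graph, spec.domain_size, 80_000, seed=spec.seed + 7)
            miss = abs(vf_est - target) / target
            if best is None or miss < best[0]:
                best = (miss, graph, dilated_ids)
            if miss < 0.04:
                break
            n_try = max(8, int(round(n_try * (target / vf_est) ** 0.8)))
            graph, dilated_ids = build(n_try)
        _, graph, dilated_ids = best

    vf = volume_fraction_mc(graph, spec.domain_size, seed=spec.seed + 7)
    graph.assign_filaments()
    extras = dict(
        n_segments=len(graph.segments),
        dilated_segment_ids=dilated_ids,
        straightness_analytic=1.0 / spec.tortuosity,
    )
    if spec.void_spec:
        extras["max_surface_distance_lower_bound"] = max(vr for _, vr in spec.void_spec)
    gt = _make_ground_truth(graph, spec, vf, None, extras)
    return graph, gt


# ---------------------------------------------------------------------------
# planar mesh (colon archetype)
# ---------------------------------------------------------------------------


def generate_planar_mesh_network(spec: NetworkSpec) -> tuple[VesselGraph, GroundTruth]:
    """A wide-diameter 2D mesh layer plus perpendicular parallel feeders.

    The mesh is a square grid of tubes of radius ``mesh_radius`` (default
    1.65 × ``mean_radius``) in a plane near the top of the domain; feeder
    vessels of radius ``mean_radius`` drop from mesh crossings to the bottom
    face, mimicking a surface mesh over parallel crypt vessels.  Mesh pitch
    equals ``mean_segment_length``; when a ``target_volume_fraction`` is set,
    the pitch is first solved for it and radii are then Monte-Carlo trimmed.
    """
    if spec.archetype != "planar_mesh":
        raise ValueError("spec.archetype must be 'planar_mesh'")
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.domain_size
    r_f = spec.mean_radius
    r_m = spec.mesh_radius if spec.mesh_radius is not None else 1.65 * r_f

    if spec.target_volume_fraction is not None:
        pitch = _solve_mesh_pitch(spec, r_m, r_f)
    else:
        pitch = spec.mean_segment_length
    if pitch <= 2.2 * r_m:
        raise ValueError("mesh pitch would make mesh tubes overlap; infeasible spec")

    # keep the mesh plane far enough from the top face that its segments are
    # not rim-filtered (tolerance grows with tube radius), but still "directly
    # beneath the surface" on organ-scale domains
    z0 = Z - min(Z / 2.0, 2.2 * r_m + 3.0)
    nx_l = max(2, int(X // pitch))
    ny_l = max(2, int(Y // pitch))
    xs = (X - (nx_l - 1) * pitch) / 2.0 + np.arange(nx_l) * pitch
    ys = (Y - (ny_l - 1) * pitch) / 2.0 + np.arange(ny_l) * pitch

    graph = VesselGraph()
    node_id = {}
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            node_id[(i, j)] = graph.add_node((x, y, z0))
    # rim stubs run to the domain faces so the mesh spans the full FOV
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            if i + 1 < len(xs):
                pts = np.array([[x, y, z0], [xs[i + 1], y, z0]])
                graph.add_segment(node_id[(i, j)], node_id[(i + 1, j)], pts, r_m)
            if j + 1 < len(ys):
                pts = np.array([[x, y, z0], [x, ys[j + 1], z0]])
                graph.add_segment(node_id[(i, j)], node_id[(i, j + 1)], pts, r_m)
    for j, y in enumerate(ys):
        for x_edge, i_edge in ((0.0, 0), (X, len(xs) - 1)):
            n_edge = graph.add_node((x_edge, y, z0))
            pts = np.array([[xs[i_edge], y, z0], [x_edge, y, z0]])
            graph.add_segment(node_id[(i_edge, j)], n_edge, pts, r_m)
    for i, x in enumerate(xs):
        for y_edge, j_edge in ((0.0, 0), (Y, len(ys) - 1)):
            n_edge = graph.add_node((x, y_edge, z0))
            pts = np.array([[x, ys[j_edge], z0], [x, y_edge, z0]])
            graph.add_segment(node_id[(i, j_edge)], n_edge, pts, r_m)

    # perpendicular feeders from mesh crossings to the bottom face
    if spec.feeder_fraction > 0:
        for (i, j), nid in list(node_id.items()):
            if rng.random() <= spec.feeder_fraction:
                x, y, _ = graph.nodes[nid]
                bottom = graph.add_node((x, y, 0.0))
                pts = np.array([[x, y, z0], [x, y, 0.0]])
                graph.add_segment(nid, bottom, pts, r_f)

    if spec.target_volume_fraction is not None:
        vf = _trim_radii_to_vf(
            graph, spec.domain_size, spec.target_volume_fraction, seed=spec.seed
        )
    else:
        vf = volume_fraction_mc(graph, spec.domain_size, seed=spec.seed)

    max_sd = None
    if spec.feeder_fraction == 0:
        # inside the mesh plane, the farthest point is the cell-diagonal midpoint
        eff_rm = float(graph.segments[0].radii[0])
        cell = float(xs[1] - xs[0]) if len(xs) > 1 else pitch
        max_sd = cell / math.sqrt(2.0) - eff_rm

    graph.assign_filaments()
    mesh_ids = [s.segment_id for s in graph.segments if abs(s.points[0][2] - z0) < 1e-9
                and abs(s.points[-1][2] - z0) < 1e-9]
    feeder_ids = [s.segment_id for s in graph.segments if s.segment_id not in set(mesh_ids)]
    extras = dict(
        mesh_pitch=pitch,
        mesh_segment_ids=mesh_ids,
        feeder_segment_ids=feeder_ids,
        mesh_mean_diameter=float(
            np.mean([2 * graph.segments[i].mean_radius for i in mesh_ids])
        ),
        feeder_mean_diameter=(
            float(np.mean([2 * graph.segments[i].mean_radius for i in feeder_ids]))
            if feeder_ids else None
        ),
        mesh_z=z0,
    )
    gt = _make_ground_truth(graph, spec, vf, max_sd, extras)
    return graph, gt


def _solve_mesh_pitch(spec: NetworkSpec, r_m: float, r_f: float) -> float:
    """Continuum pitch estimate for a target volume fraction (pre-trim)."""
    X, Y, Z = spec.domain_size
    vol = X * Y * Z
    target = spec.target_volume_fraction

    def vf_of(pitch: float) -> float:
        n_lines = X / pitch + Y / pitch
        mesh_vol = n_lines * ((X + Y) / 2) * math.pi * r_m**2
        n_nodes = (X / pitch) * (Y / pitch)
        feeder_vol = spec.feeder_fraction * n_nodes * Z * math.pi * r_f**2
        return (mesh_vol + feeder_vol) / vol

    lo, hi = 2.3 * r_m, max(X, Y)
    if vf_of(lo) < target:
        raise ValueError("target volume fraction infeasible for a planar mesh")
    if vf_of(hi) > target:
        return hi
    return float(optimize.brentq(lambda p: vf_of(p) - target, lo, hi))


# ---------------------------------------------------------------------------
# tumor archetype
# ---------------------------------------------------------------------------


def generate_tumor_network(spec: NetworkSpec) -> tuple[VesselGraph, GroundTruth]:
    """Heterogeneous, tortuous network with avascular voids and dilated stubs.

    Vessels grow in clusters of uneven density (Dirichlet-weighted budgets),
    never enter the hard void spheres of ``void_spec``, and a configurable
    fraction of the *short* segments is dilated (radius × ``dilation_factor``),
    reproducing the short isolated dilated sections typical of tumor
    vasculature.  With ``dilated_fraction = 0``, ``tortuosity = 1`` and one
    cluster, the construction reduces to the random-arc generator.
    """
    if spec.archetype != "tumor":
        raise ValueError("spec.archetype must be 'tumor'")
    X, Y, Z = spec.domain_size
    usable = np.array(spec.domain_size).prod()
    void_vol = sum(4 / 3 * math.pi * vr**3 for _, vr in spec.void_spec)
    if void_vol >= usable:
        raise ValueError("void spheres cover the entire domain")
    graph, gt = _grow_arcs(spec, clustered=True)
    if spec.void_spec:
        for seg in graph.segments:
            for center, vr in spec.void_spec:
                d = np.linalg.norm(seg.points - np.asarray(center, float), axis=1)
                assert np.all(d >= vr), "void exclusion violated"
    return graph, gt


_GENERATORS = {
    "parallel_fiber": generate_parallel_fiber_network,
    "random_arc": generate_random_arc_network,
    "planar_mesh": generate_planar_mesh_network,
    "tumor": generate_tumor_network,
}


def generate_network(spec: NetworkSpec) -> tuple[VesselGraph, GroundTruth]:
    """Dispatch to the archetype's generator."""
    return _GENERATORS[spec.archetype](spec)
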