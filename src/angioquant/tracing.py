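"""Vessel tracing: mask → centerline skeleton → vessel graph → morphometrics.

The traced entities follow the dendrite-derived vocabulary of filament
tracing tools: a *segment* is the centerline between two bifurcations (or a
bifurcation and an endpoint), a *filament* is a connected network.  Per
segment we measure arc length (µm, anisotropy-aware), mean diameter (twice
the interior Euclidean distance transform sampled along the centerline),
straightness (chord / arc, in (0, 1]) and the XY-plane orientation angle of
the chord.  Segments cut off at the rim of the field of view are flagged and
excluded from statistics, since partial segments would bias every length and
straightness estimate downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from ._thinning import skeletonize_3d
from .graph import VesselGraph, VesselSegment
from .segmentation import VesselMask
from .volume import RasterVolume

__all__ = [
    "SegmentRecord",
    "skeletonize_mask",
    "build_vessel_graph",
    "measure_segment",
    "segment_table",
    "remove_boundary_segments",
    "center_orientation_distribution",
    "circular_sd",
    "prune_spurs",
    "contract_junction_bridges",
    "trace_mask",
]

_NEIGHBOR_OFFSETS = np.array(
    [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=int
)


@dataclass
class SegmentRecord:
    """Morphometrics of one vessel segment."""

    segment_id: int
    filament_id: int
    length: float            # µm, polyline arc length
    mean_diameter: float     # µm
    straightness: float      # chord/arc, 0 for closed loops
    orientation_xy: float    # degrees in (-90, 90]
    touches_boundary: bool
    is_loop: bool = False


def skeletonize_mask(mask: RasterVolume | VesselMask) -> RasterVolume:
    """Thin a binary mask to a one-voxel-wide, topology-preserving skeleton.

    Uses homotopic distance-ordered thinning (see :mod:`angioquant._thinning`):
    component count, loops and cavities of the mask are preserved exactly.
    """
    vol = mask.mask if isinstance(mask, VesselMask) else mask
    data = vol.voxels.astype(bool)
    if not data.any():
        return vol.with_voxels(np.zeros_like(data))
    skel = skeletonize_3d(data, spacing=vol.spacing)
    return vol.with_voxels(skel)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    counts = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
    return counts * skel


def build_vessel_graph(
    skeleton: RasterVolume,
    edt: np.ndarray | None = None,
    min_radius: float | None = None,
    radius_offset: float | None = None,
) -> VesselGraph:
    """Convert a voxel skeleton into a vessel graph.

    Nodes are skeleton voxels with ≠ 2 26-neighbours; clusters of adjacent
    node voxels (thinning routinely produces 2–3 touching branch voxels at
    one anatomical bifurcation) are collapsed to their centroid.  Segments
    are maximal paths of degree-2 voxels between nodes; a pure cycle with no
    branch voxel becomes a single segment with coincident endpoints.

    ``edt`` is the interior Euclidean distance transform of the *mask* (µm);
    sampled at centerline voxels it provides the per-point radius.  The
    discrete centerline sits up to half a voxel off the true axis, which
    makes the raw EDT sample underestimate the radius; a compensation of
    0.38 × the local transverse voxel pitch (the expected center-to-axis
    distance under a uniform sub-voxel offset, evaluated per point from the
    polyline tangent so anisotropic stacks are handled) is added by default.
    Pass ``radius_offset`` to use a fixed offset instead, or 0 to disable.
    Without an EDT, radii default to half the smallest spacing.
    """
    skel = skeleton.voxels.astype(bool)
    spacing = np.asarray(skeleton.spacing)
    if min_radius is None:
        min_radius = 0.5 * float(spacing.min())
    graph = VesselGraph()
    if not skel.any():
        return graph

    counts = _neighbor_counts(skel)
    node_mask = skel & (counts != 2)
    # merge adjacent branch/end voxels into single nodes
    node_labels, n_clusters = ndimage.label(node_mask, structure=np.ones((3, 3, 3)))

    def radius_at(idx: np.ndarray) -> float:
        if edt is None:
            return min_radius
        return max(float(edt[tuple(idx)]), min_radius)

    cluster_centroid: dict[int, np.ndarray] = {}
    cluster_node: dict[int, int] = {}
    cluster_radius: dict[int, float] = {}
    if n_clusters:
        centroids = ndimage.center_of_mass(node_mask, node_labels, range(1, n_clusters + 1))
        for cid, com in enumerate(centroids, start=1):
            pos = np.asarray(com) * spacing
            cluster_centroid[cid] = pos
            cluster_node[cid] = graph.add_node(pos)
        for cid in range(1, n_clusters + 1):
            vox = np.argwhere(node_labels == cid)
            cluster_radius[cid] = float(np.mean([radius_at(v) for v in vox]))

    in_bounds = lambda idx: np.all(idx >= 0) and np.all(idx < skel.shape)

    def neighbors(idx: np.ndarray) -> list[np.ndarray]:
        out = []
        for off in _NEIGHBOR_OFFSETS:
            j = idx + off
            if in_bounds(j) and skel[tuple(j)]:
                out.append(j)
        return out

    path_mask = skel & (counts == 2)
    visited = np.zeros_like(skel, dtype=bool)

    def walk(start_cid: int, first: np.ndarray) -> None:
        """Follow a degree-2 path from a node cluster until the next cluster."""
        pts_idx = [first]
        visited[tuple(first)] = True
        current = first
        prev_cluster = start_cid
        while True:
            nbrs = neighbors(current)
            nxt = None
            end_cid = None
            for j in nbrs:
                cid = node_labels[tuple(j)]
                if cid and not (len(pts_idx) == 1 and cid == prev_cluster):
                    end_cid = cid
                elif path_mask[tuple(j)] and not visited[tuple(j)]:
                    nxt = j
            if end_cid is not None and (nxt is None or len(pts_idx) >= 1):
                _emit(start_cid, end_cid, pts_idx)
                return
            if nxt is None:
                # dead-ends into already-visited voxels (tight cycles): drop
                return
            visited[tuple(nxt)] = True
            pts_idx.append(nxt)
            current = nxt

    def _emit(cid_a: int, cid_b: int, pts_idx: list[np.ndarray]) -> None:
        pts = [cluster_centroid[cid_a]]
        radii = [cluster_radius[cid_a]]
        for idx in pts_idx:
            pts.append(idx * spacing)
            radii.append(radius_at(idx))
        pts.append(cluster_centroid[cid_b])
        radii.append(cluster_radius[cid_b])
        graph.add_segment(
            cluster_node[cid_a], cluster_node[cid_b], np.asarray(pts), np.asarray(radii)
        )

    # paths emanating from node clusters
    emitted_contacts: set[tuple[int, int]] = set()
    for cid in range(1, n_clusters + 1):
        for vox in np.argwhere(node_labels == cid):
            for j in neighbors(vox):
                jt = tuple(j)
                if path_mask[jt] and not visited[jt]:
                    walk(cid, j)
                cid_j = node_labels[jt]
                if cid_j and cid_j > cid:
                    # direct cluster-cluster contact: unit-length segment
                    key = (cid, cid_j)
                    if key not in emitted_contacts:
                        emitted_contacts.add(key)
                        pts = np.array([cluster_centroid[cid], cluster_centroid[cid_j]])
                        if np.linalg.norm(pts[1] - pts[0]) > 1e-9:
                            graph.add_segment(
                                cluster_node[cid], cluster_node[cid_j], pts,
                                np.array([cluster_radius[cid], cluster_radius[cid_j]]),
                            )

    # pure cycles: components made only of degree-2 voxels
    remaining = path_mask & ~visited
    for idx in np.argwhere(remaining):
        it = tuple(idx)
        if visited[it]:
            continue
        loop_pts = [idx]
        visited[it] = True
        current = idx
        while True:
            nxt = None
            for j in neighbors(current):
                if path_mask[tuple(j)] and not visited[tuple(j)]:
                    nxt = j
                    break
            if nxt is None:
                break
            visited[tuple(nxt)] = True
            loop_pts.append(nxt)
            current = nxt
        if len(loop_pts) < 3:
            continue
        nid = graph.add_node(loop_pts[0] * spacing)
        pts = np.vstack([p * spacing for p in loop_pts] + [loop_pts[0] * spacing])
        radii = np.array([radius_at(p) for p in loop_pts] + [radius_at(loop_pts[0])])
        graph.add_segment(nid, nid, pts, radii)

    if edt is not None:
        _apply_radius_offset(graph, spacing, radius_offset)
    graph.assign_filaments()
    return graph


def _apply_radius_offset(
    graph: VesselGraph, spacing: np.ndarray, radius_offset: float | None
) -> None:
    """Add the sub-voxel centerline-offset compensation to per-point radii."""
    if radius_offset is not None:
        if radius_offset:
            for seg in graph.segments:
                seg.radii = seg.radii + radius_offset
        return
    s = np.asarray(spacing, dtype=float)
    for seg in graph.segments:
        tang = np.gradient(seg.points, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        # transverse pitch: geometric mean of the two spacings least aligned
        # with the local tangent
        most_aligned = np.argmax(np.abs(tang / norm), axis=1)
        delta_t = np.sqrt(s.prod() / s[most_aligned])
        seg.radii = seg.radii + 0.38 * delta_t


def contract_junction_bridges(graph: VesselGraph, factor: float = 2.0, passes: int = 3) -> VesselGraph:
    """Collapse very short junction-to-junction segments into single nodes.

    A voxel-grid X-crossing routinely thins into two Y-nodes joined by a
    bridge a few voxels long; anatomically it is one bifurcation.  Segments
    with both endpoints of degree ≥ 3 and length < ``factor`` × their mean
    radius are contracted: the two nodes merge at their midpoint and the
    incident polylines are re-anchored there (recovering the length the
    bridge absorbed).
    """
    g = graph
    for _ in range(passes):
        nxg = g.to_networkx()
        deg = dict(nxg.degree())
        bridges = [
            s for s in g.segments
            if not s.is_loop
            and deg.get(s.node_a, 0) >= 3 and deg.get(s.node_b, 0) >= 3
            and s.length < factor * s.mean_radius
        ]
        if not bridges:
            break
        remap: dict[int, int] = {}

        def resolve(n: int) -> int:
            while n in remap:
                n = remap[n]
            return n

        node_pos = {nid: pos.copy() for nid, pos in g.nodes.items()}
        touched: set[int] = set()
        drop: set[int] = set()
        for s in bridges:
            a, b = resolve(s.node_a), resolve(s.node_b)
            if a == b:
                drop.add(s.segment_id)
                continue
            if a in touched or b in touched:
                continue
            node_pos[a] = 0.5 * (node_pos[a] + node_pos[b])
            remap[b] = a
            touched.update((a, b))
            drop.add(s.segment_id)
        if not drop:
            break
        out = VesselGraph(nodes={})
        kept_nodes: dict[int, int] = {}
        for s in g.segments:
            if s.segment_id in drop:
                continue
            na, nb = resolve(s.node_a), resolve(s.node_b)
            for n in (na, nb):
                if n not in kept_nodes:
                    kept_nodes[n] = out.add_node(node_pos[n])
            pts = s.points.copy()
            pts[0] = node_pos[na]
            pts[-1] = node_pos[nb]
            out.add_segment(kept_nodes[na], kept_nodes[nb], pts, s.radii)
        g = out
    g.assign_filaments()
    return g


def prune_spurs(graph: VesselGraph, factor: float = 2.0, passes: int = 2) -> VesselGraph:
    """Remove terminal spurs shorter than ``factor`` × their mean radius.

    Thinning sprouts short side-branches wherever the tube surface is rough;
    left in place they inflate segment counts and deflate mean lengths.
    After each removal pass, chains through now-degree-2 nodes are merged
    back into single segments.
    """
    g = graph
    for _ in range(passes):
        nxg = g.to_networkx()
        degree = dict(nxg.degree())
        keep = []
        removed = False
        for seg in g.segments:
            is_leaf = degree.get(seg.node_a, 0) == 1 or degree.get(seg.node_b, 0) == 1
            if is_leaf and not seg.is_loop and seg.length < factor * seg.mean_radius:
                removed = True
                continue
            keep.append(seg)
        g = _rebuild(g.nodes, keep)
        g = _merge_degree2(g)
        if not removed:
            break
    g.assign_filaments()
    return g


def _rebuild(nodes: dict[int, np.ndarray], segments: list[VesselSegment]) -> VesselGraph:
    used = {s.node_a for s in segments} | {s.node_b for s in segments}
    g = VesselGraph(nodes={nid: pos for nid, pos in nodes.items() if nid in used})
    for seg in segments:
        g.add_segment(seg.node_a, seg.node_b, seg.points, seg.radii)
    return g


def _merge_degree2(graph: VesselGraph) -> VesselGraph:
    """Stitch pairs of segments meeting at a degree-2 node into one."""
    segs = {s.segment_id: s for s in graph.segments}
    incident: dict[int, list[int]] = {}
    for s in graph.segments:
        incident.setdefault(s.node_a, []).append(s.segment_id)
        incident.setdefault(s.node_b, []).append(s.segment_id)
    changed = True
    while changed:
        changed = False
        for nid, sids in list(incident.items()):
            sids = [s for s in sids if s in segs]
            incident[nid] = sids
            if len(sids) != 2 or sids[0] == sids[1]:
                continue
            a, b = segs[sids[0]], segs[sids[1]]
            if a.is_loop or b.is_loop:
                continue
            # orient a to end at nid, b to start at nid
            if a.node_a == nid:
                pts_a, rad_a, far_a = a.points[::-1], a.radii[::-1], a.node_b
            else:
                pts_a, rad_a, far_a = a.points, a.radii, a.node_a
            if b.node_a == nid:
                pts_b, rad_b, far_b = b.points, b.radii, b.node_b
            else:
                pts_b, rad_b, far_b = b.points[::-1], b.radii[::-1], b.node_a
            merged = VesselSegment(
                a.segment_id,
                far_a,
                far_b,
                np.vstack([pts_a, pts_b[1:]]),
                np.concatenate([rad_a, rad_b[1:]]),
            )
            del segs[b.segment_id]
            segs[a.segment_id] = merged
            incident[nid] = []
            for end in (far_a, far_b):
                lst = incident.setdefault(end, [])
                if b.segment_id in lst:
                    lst[lst.index(b.segment_id)] = a.segment_id
            changed = True
    return _rebuild(graph.nodes, list(segs.values()))


def measure_segment(
    points: np.ndarray,
    radii: np.ndarray,
    segment_id: int = 0,
    filament_id: int = -1,
    touches_boundary: bool = False,
    trim_endpoint_radii: bool = True,
) -> SegmentRecord:
    """Morphometrics of a single centerline polyline (positions in µm).

    ``trim_endpoint_radii`` drops the first/last radius sample from the
    diameter average when enough interior samples exist, because endpoint
    samples sit inside junction blobs where the distance transform
    overestimates the tube radius.
    """
    pts = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(steps.sum())
    if length <= 0:
        raise ValueError("degenerate segment with zero length")
    chord = pts[-1] - pts[0]
    chord_len = float(np.linalg.norm(chord))
    is_loop = chord_len < 1e-9
    straightness = 0.0 if is_loop else chord_len / length

    r = radii
    if trim_endpoint_radii and len(radii) >= 4:
        r = radii[1:-1]
    mean_diameter = float(2.0 * r.mean())

    if is_loop or (abs(chord[0]) < 1e-12 and abs(chord[1]) < 1e-12):
        angle = 0.0
    else:
        angle = float(np.degrees(np.arctan2(chord[1], chord[0])))
    angle = _to_axial(angle)
    return SegmentRecord(
        segment_id=segment_id,
        filament_id=filament_id,
        length=length,
        mean_diameter=mean_diameter,
        straightness=straightness,
        orientation_xy=angle,
        touches_boundary=touches_boundary,
        is_loop=is_loop,
    )


def _to_axial(angle_deg: float) -> float:
    """Map an angle to the axial range (-90, 90] (orientation mod 180°)."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def segment_table(
    graph: VesselGraph,
    bounds: tuple[float, float, float] | None = None,
    boundary_tol: tuple[float, float, float] | float = 1.0,
    metadata: dict | None = None,
    trim_endpoint_radii: bool = True,
    boundary_radius_factor: float = 2.0,
) -> pd.DataFrame:
    """Tabulate per-segment morphometrics of a vessel graph.

    ``bounds`` is the physical FOV extent (µm); segment endpoints within
    ``boundary_tol`` (one voxel spacing per axis, typically) plus
    ``boundary_radius_factor`` × the segment's own radius of a face are
    flagged ``touches_boundary`` — thinning retracts the skeleton tip of a
    cut-off tube by roughly one tube radius, so a bare one-voxel test would
    miss most rim casualties.  Extra ``metadata`` key/values are attached in
    ``DataFrame.attrs`` and as constant columns where scalar.
    """
    base_tol = np.broadcast_to(np.asarray(boundary_tol, dtype=float), (3,))
    rows = []
    for seg in graph.segments:
        touches = False
        if bounds is not None:
            b = np.asarray(bounds, dtype=float)
            tol = base_tol + boundary_radius_factor * seg.mean_radius
            for pt in (seg.points[0], seg.points[-1]):
                if np.any(pt <= tol) or np.any(b - pt <= tol):
                    touches = True
        rec = measure_segment(
            seg.points, seg.radii, seg.segment_id, seg.filament_id, touches,
            trim_endpoint_radii,
        )
        rows.append(
            dict(
                segment_id=rec.segment_id,
                filament_id=rec.filament_id,
                length=rec.length,
                mean_diameter=rec.mean_diameter,
                straightness=rec.straightness,
                orientation_xy=rec.orientation_xy,
                touches_boundary=rec.touches_boundary,
                is_loop=rec.is_loop,
                x_start=seg.points[0][0], y_start=seg.points[0][1], z_start=seg.points[0][2],
                x_end=seg.points[-1][0], y_end=seg.points[-1][1], z_end=seg.points[-1][2],
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "segment_id", "filament_id", "length", "mean_diameter", "straightness",
            "orientation_xy", "touches_boundary", "is_loop",
            "x_start", "y_start", "z_start", "x_end", "y_end", "z_end",
        ],
    )
    df.attrs["metadata"] = dict(metadata or {})
    for k, v in (metadata or {}).items():
        if np.isscalar(v):
            df[k] = v
    return df


def remove_boundary_segments(table: pd.DataFrame, bounds=None, boundary_tol=None) -> pd.DataFrame:
    """Drop rim-cut segments (their partial lengths would falsify statistics).

    If the table already carries the ``touches_boundary`` flag (the default
    produced by :func:`segment_table`), ``bounds`` is not needed; otherwise
    the flag is recomputed from the endpoint columns.
    """
    df = table
    if bounds is not None:
        tol = np.broadcast_to(np.asarray(boundary_tol if boundary_tol is not None else 1.0,
                                         dtype=float), (3,))
        b = np.asarray(bounds, dtype=float)
        start = df[["x_start", "y_start", "z_start"]].to_numpy()
        end = df[["x_end", "y_end", "z_end"]].to_numpy()
        touches = np.zeros(len(df), dtype=bool)
        for pts in (start, end):
            touches |= np.any(pts <= tol, axis=1) | np.any(b - pts <= tol, axis=1)
        df = df.assign(touches_boundary=touches)
    out = df[~df["touches_boundary"]].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def center_orientation_distribution(
    angles_deg: np.ndarray, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift axial angles so the modal orientation sits at 0°.

    Angles are 180°-periodic; the mode of the ``bin_width``-degree histogram
    is subtracted and the result mapped back to (-90, 90].  Returns
    ``(centered_angles, bin_centers, frequencies)`` of the centered
    histogram (frequencies sum to 1).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    axial = _to_axial_array(a)
    hist, _ = np.histogram(axial, bins=edges)
    k = int(np.argmax(hist))
    in_mode = (axial >= edges[k]) & (axial < edges[k + 1])
    if k == len(hist) - 1:
        in_mode |= axial == edges[-1]
    # refine the modal bin to the axial circular mean of its members, so that
    # e.g. a perfectly aligned sample centers exactly on 0°
    mode_center = float(
        np.degrees(np.angle(np.exp(2j * np.radians(axial[in_mode])).mean())) / 2.0
    )
    centered = _to_axial_array(a - mode_center)
    hist2, _ = np.histogram(centered, bins=edges)
    freqs = hist2 / hist2.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centered, centers, freqs


def _to_axial_array(a: np.ndarray) -> np.ndarray:
    out = (np.asarray(a, dtype=float) + 90.0) % 180.0 - 90.0
    out[out == -90.0] = 90.0
    return out


def circular_sd(angles_deg: np.ndarray) -> float:
    """Circular standard deviation (degrees) of axial (180°-periodic) data."""
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    R = float(np.abs(np.exp(1j * a).mean()))
    R = min(max(R, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(R)) / 2.0))


def trace_mask(
    mask: VesselMask | RasterVolume,
    prune_factor: float = 2.0,
    junction_merge_factor: float = 2.0,
    metadata: dict | None = None,
    trim_endpoint_radii: bool = True,
) -> tuple[VesselGraph, pd.DataFrame]:
    """Full tracing stage: skeletonize → graph → clean up → tabulate.

    Cleanup removes terminal spurs shorter than ``prune_factor`` × radius
    and contracts junction bridges shorter than ``junction_merge_factor`` ×
    radius (both thinning artifacts); set a factor to 0 to disable.
    """
    vol = mask.mask if isinstance(mask, VesselMask) else mask
    skel = skeletonize_mask(vol)
    edt = ndimage.distance_transform_edt(vol.voxels.astype(bool), sampling=vol.spacing)
    graph = build_vessel_graph(skel, edt=edt)
    if prune_factor > 0:
        graph = prune_spurs(graph, factor=prune_factor)
    if junction_merge_factor > 0:
        graph = contract_junction_bridges(graph, factor=junction_merge_factor)
    bounds = tuple((n - 1) * s for n, s in zip(vol.shape, vol.spacing))
    table = segment_table(
        graph, bounds=bounds, boundary_tol=vol.spacing, metadata=metadata,
        trim_endpoint_radii=trim_endpoint_radii,
    )
    return graph, table
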