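"""Vessel centerline networks.

A :class:`VesselGraph` is the traced representation of a vascular network:
nodes are bifurcations or endpoints, segments ("dendrites" in the tracing
tool's dendrite-derived vocabulary) are the polyline centerlines between two
nodes, carrying a per-point radius.  A *filament* is a connected component
of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["VesselSegment", "VesselGraph", "polyline_arc_length", "segment_straightness"]


def polyline_arc_length(points: np.ndarray) -> float:
    """Arc length of an (N, 3) polyline: sum of consecutive Euclidean steps."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (N>=2, 3) array")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def segment_straightness(points: np.ndarray) -> float:
    """Chord length over arc length; 1 for a straight centerline, 0 for a loop."""
    pts = np.asarray(points, dtype=float)
    arc = polyline_arc_length(pts)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if arc == 0:
        raise ValueError("degenerate zero-length polyline")
    return chord / arc


@dataclass
class VesselSegment:
    """One vessel segment between two nodes.

    ``points`` is the (N, 3) centerline polyline in µm, ``radii`` the (N,)
    per-point radius in µm.  The first/last points coincide with the
    positions of ``node_a``/``node_b``.
    """

    segment_id: int
    node_a: int
    node_b: int
    points: np.ndarray
    radii: np.ndarray
    filament_id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.radii.size == 1:
            self.radii = np.full(len(self.points), self.radii[0])
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("segment polyline must be (N>=2, 3)")
        if len(self.radii) != len(self.points):
            raise ValueError("radii must match polyline length")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def length(self) -> float:
        return polyline_arc_length(self.points)

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    @property
    def is_loop(self) -> bool:
        return self.node_a == self.node_b


@dataclass
class VesselGraph:
    """Centerline network: nodes (id → position µm) plus segments."""

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    segments: list[VesselSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = {int(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}

    # -- construction -----------------------------------------------------
    def add_node(self, position: np.ndarray) -> int:
        nid = max(self.nodes, default=-1) + 1
        self.nodes[nid] = np.asarray(position, dtype=float)
        return nid

    def add_segment(
        self,
        node_a: int,
        node_b: int,
        points: np.ndarray,
        radii: np.ndarray | float,
    ) -> VesselSegment:
        seg = VesselSegment(len(self.segments), node_a, node_b, points, np.asarray(radii))
        self.segments.append(seg)
        return seg

    # -- derived structure ------------------------------------------------
    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for nid, pos in self.nodes.items():
            g.add_node(nid, position=pos)
        for seg in self.segments:
            g.add_edge(seg.node_a, seg.node_b, key=seg.segment_id, segment=seg)
        return g

    def assign_filaments(self) -> None:
        """Label every node/segment with its connected component id.

        Components are numbered by decreasing total centerline length so the
        main filament is always filament 0.
        """
        g = self.to_networkx()
        comps = list(nx.connected_components(g))
        lengths = []
        for comp in comps:
            total = sum(
                s.length for s in self.segments if s.node_a in comp or s.node_b in comp
            )
            lengths.append(total)
        order = np.argsort(lengths)[::-1]
        node_to_fil: dict[int, int] = {}
        for fil_id, ci in enumerate(order):
            for nid in comps[ci]:
                node_to_fil[nid] = fil_id
        for seg in self.segments:
            seg.filament_id = node_to_fil.get(seg.node_a, -1)

    @property
    def n_filaments(self) -> int:
        g = self.to_networkx()
        return nx.number_connected_components(g) if g.number_of_nodes() else 0

    @property
    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([s.points for s in self.segments]) if self.segments else np.zeros((1, 3))
        return pts.min(axis=0), pts.max(axis=0)

    def validate(self, atol: float = 1e-6) -> None:
        """Check structural invariants (endpoint coincidence, positive radii)."""
        for seg in self.segments:
            for nid, pt in ((seg.node_a, seg.points[0]), (seg.node_b, seg.points[-1])):
                if nid not in self.nodes:
                    raise ValueError(f"segment {seg.segment_id} references unknown node {nid}")
                if not np.allclose(self.nodes[nid], pt, atol=atol):
                    raise ValueError(
                        f"segment {seg.segment_id} endpoint does not coincide with node {nid}"
                    )
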