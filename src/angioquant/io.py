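"""File formats: TIFF stacks, SWC / GraphML vessel graphs, CSV tables.

Multi-page TIFF is page-major (z, y, x); the in-memory convention is
``[x, y, z]``, so reading/writing transposes.  Voxel spacing in TIFF
metadata is treated as advisory only — stacks from acquisition software
routinely carry wrong or missing calibration — so the caller must state the
spacing explicitly (config/CLI), and a sidecar JSON written next to every
exported volume records the authoritative value.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .graph import VesselGraph
from .volume import RasterVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_swc",
    "read_swc",
    "write_graphml",
    "read_graphml",
    "read_imaris_table",
]


def read_volume(path: str | Path, spacing: tuple[float, float, float] | None = None) -> RasterVolume:
    """Read a multi-page TIFF stack as a :class:`RasterVolume`.

    ``spacing`` (µm, (sx, sy, sz)) is required unless a sidecar JSON written
    by :func:`write_volume` sits next to the file; an explicit argument
    always wins over the sidecar.  Raises distinct errors for a non-TIFF
    file, mismatched page shapes, and absent spacing.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise ValueError(f"{path}: TIFF pages have mismatched shapes {shapes}")
            data = tf.asarray()
    except tifffile.TiffFileError as err:
        raise ValueError(f"{path} is not a readable TIFF stack: {err}") from err
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    if spacing is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta["spacing"])
        else:
            raise ValueError(
                f"{path}: voxel spacing not provided and no sidecar JSON found; "
                "stack metadata is advisory only — pass spacing explicitly"
            )
    # pages are (z, y, x); internal order is (x, y, z)
    return RasterVolume(np.ascontiguousarray(data.T), tuple(spacing), check_shape=False)


def write_volume(volume: RasterVolume, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a volume as multi-page TIFF plus a spacing sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(path, np.ascontiguousarray(data.T), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = dict(spacing=list(volume.spacing), origin=list(volume.origin),
                shape=list(volume.shape))
    for k, v in (extra_meta or {}).items():
        meta.setdefault(k, v)
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

_SWC_TYPE = 2  # "axon" slot, conventionally reused for vessel centerlines


def write_swc(graph: VesselGraph, path: str | Path) -> Path:
    """Write the network as SWC, one tree per filament.

    SWC encodes rooted trees (sample, type, x, y, z, radius, parent).  Each
    filament is written as a BFS spanning tree from an arbitrary root; edges
    that would close cycles are dropped, so SWC export is lossy for looped
    networks (GraphML is the lossless format).  Radii are in µm.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# generated by angioquant", "# columns: id type x y z radius parent"]
    counter = 1
    nxg = graph.to_networkx()
    seg_by_key = {s.segment_id: s for s in graph.segments}
    for comp in nx.connected_components(nxg):
        root = min(comp)
        node_sample: dict[int, int] = {}
        stack = [(root, -1)]
        seen_edges = set()
        while stack:
            nid, parent_sample = stack.pop()
            if nid in node_sample:
                continue
            pos = graph.nodes[nid]
            # node radius: mean radius of incident segments at this end
            rads = [
                seg_by_key[k].radii[0 if s.node_a == nid else -1]
                for _, _, k in nxg.edges(nid, keys=True)
                for s in (seg_by_key[k],)
            ]
            radius = float(np.mean(rads)) if rads else 1.0
            lines.append(
                f"{counter} {_SWC_TYPE} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f} "
                f"{radius:.4f} {parent_sample}"
            )
            node_sample[nid] = counter
            counter += 1
            for _, other, key in nxg.edges(nid, keys=True):
                if key in seen_edges or other in node_sample:
                    continue
                seen_edges.add(key)
                seg = seg_by_key[key]
                pts, rads_ = seg.points, seg.radii
                if seg.node_a != nid:
                    pts, rads_ = pts[::-1], rads_[::-1]
                parent = node_sample[nid]
                for p, r in zip(pts[1:-1], rads_[1:-1]):
                    lines.append(
                        f"{counter} {_SWC_TYPE} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} "
                        f"{r:.4f} {parent}"
                    )
                    parent = counter
                    counter += 1
                stack.append((other, parent))
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_swc(path: str | Path) -> VesselGraph:
    """Read an SWC file back into a vessel graph.

    Chains of intermediate samples become segment polylines; samples with
    ≠ 2 neighbours (roots, tips, branch points) become graph nodes.
    """
    samples: dict[int, tuple[np.ndarray, float, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        sid, parent = int(f[0]), int(f[6])
        samples[sid] = (np.array([float(f[2]), float(f[3]), float(f[4])]), float(f[5]), parent)
    children: dict[int, list[int]] = {s: [] for s in samples}
    for sid, (_, _, parent) in samples.items():
        if parent != -1:
            children.setdefault(parent, []).append(sid)
    degree = {s: len(children.get(s, [])) + (0 if samples[s][2] == -1 else 1) for s in samples}
    graph = VesselGraph()
    node_of: dict[int, int] = {}
    for sid in samples:
        if degree[sid] != 2 or samples[sid][2] == -1:
            node_of[sid] = graph.add_node(samples[sid][0])
    for start in node_of:
        for child in children.get(start, []):
            pts = [samples[start][0]]
            rads = [samples[start][1]]
            cur = child
            while cur not in node_of:
                pts.append(samples[cur][0])
                rads.append(samples[cur][1])
                nxt = children.get(cur, [])
                if not nxt:
                    break
                cur = nxt[0]
            if cur in node_of:
                pts.append(samples[cur][0])
                rads.append(samples[cur][1])
                graph.add_segment(node_of[start], node_of[cur], np.asarray(pts), np.asarray(rads))
    graph.assign_filaments()
    return graph


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def write_graphml(graph: VesselGraph, path: str | Path) -> Path:
    """Lossless GraphML export: polylines/radii serialized as JSON attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = nx.MultiGraph()
    for nid, pos in graph.nodes.items():
        g.add_node(nid, x=float(pos[0]), y=float(pos[1]), z=float(pos[2]))
    for seg in graph.segments:
        g.add_edge(
            seg.node_a,
            seg.node_b,
            key=seg.segment_id,
            length=seg.length,
            mean_radius=seg.mean_radius,
            filament_id=seg.filament_id,
            polyline=json.dumps(seg.points.tolist()),
            radii=json.dumps(seg.radii.tolist()),
        )
    nx.write_graphml(g, path)
    return path


def read_graphml(path: str | Path) -> VesselGraph:
    g = nx.read_graphml(path, node_type=int, force_multigraph=True)
    graph = VesselGraph(
        nodes={n: np.array([d["x"], d["y"], d["z"]]) for n, d in g.nodes(data=True)}
    )
    for a, b, data in sorted(g.edges(data=True), key=lambda e: int(e[2].get("filament_id", 0))):
        graph.add_segment(
            a, b, np.array(json.loads(data["polyline"])), np.array(json.loads(data["radii"]))
        )
    graph.assign_filaments()
    return graph


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------

_IMARIS_COLUMNS = {
    "Dendrite Length": "length",
    "Dendrite Mean Diameter": "mean_diameter",
    "Dendrite Straightness": "straightness",
    "FilamentID": "filament_id",
    "ID": "segment_id",
}


def read_imaris_table(path: str | Path) -> pd.DataFrame:
    """Read a filament-statistics spreadsheet in the Imaris CSV dialect.

    Maps the dendrite-vocabulary column names onto the package's segment
    table columns; unknown columns are kept as-is.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in _IMARIS_COLUMNS.items() if k in df.columns})
    missing = {"length", "mean_diameter"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expected columns {sorted(missing)}")
    if "touches_boundary" not in df:
        df["touches_boundary"] = False
    return df
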