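"""Readers and writers for pipeline artifacts.

Volumes travel as TIFF / OME-TIFF (voxel spacing from OME metadata or an
explicit override — never guessed, since anisotropy matters downstream);
graphs as JSON (and optionally GraphML); tracks and kinematics as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .graphs import AJGraph, Cell, CellGraph
from .tracker import CellTrack
from .volume import ImageVolume

__all__ = [
    "read_timelapse",
    "write_timelapse",
    "write_graph",
    "read_graph",
    "write_cell_graph",
    "read_cell_graph",
    "tracks_to_dataframe",
]


def _ome_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        import xml.etree.ElementTree as ET

        meta = tif.ome_metadata
        if not meta:
            return None
        root = ET.fromstring(meta)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        sz = px.get("PhysicalSizeZ")
        sy = px.get("PhysicalSizeY")
        sx = px.get("PhysicalSizeX")
        if sz is None or sy is None or sx is None:
            return None
        return float(sz), float(sy), float(sx)
    except Exception:
        return None


def read_timelapse(
    path: str | Path, spacing_override: tuple[float, float, float] | None = None
) -> list[ImageVolume]:
    """Read a time lapse from a multi-page TIFF or a directory of TIFFs.

    Frames are ordered by time (page order, or sorted file name).  Voxel
    spacing comes from OME metadata when present, otherwise from the
    override; with neither, an error is raised — downstream filtering needs
    physical units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stacks: list[np.ndarray] = []
    spacing = spacing_override
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        for f in files:
            with tifffile.TiffFile(f) as tif:
                if spacing is None:
                    spacing = _ome_spacing(tif)
                stacks.append(tif.asarray())
    else:
        with tifffile.TiffFile(path) as tif:
            if spacing is None:
                spacing = _ome_spacing(tif)
            arr = tif.asarray()
        if arr.ndim == 4:
            stacks = [arr[i] for i in range(arr.shape[0])]
        elif arr.ndim == 3:
            stacks = [arr]
        else:
            raise ValueError(f"expected a 3D or 4D TIFF, got ndim={arr.ndim}")
    if spacing is None:
        raise ValueError(
            "voxel spacing unavailable: no OME metadata found and no override given"
        )
    shape0 = stacks[0].shape
    for i, s in enumerate(stacks):
        if s.shape != shape0:
            raise ValueError(f"frame {i} has shape {s.shape}, expected {shape0}")
    return [ImageVolume(data=s, spacing=spacing, time_index=i) for i, s in enumerate(stacks)]


def write_timelapse(volumes: list[ImageVolume], path: str | Path) -> None:
    """Write frames as one OME-TIFF with physical voxel sizes recorded."""
    if not volumes:
        raise ValueError("nothing to write")
    sz, sy, sx = volumes[0].spacing
    data = np.stack([v.data for v in volumes]).astype(np.float32)
    tifffile.imwrite(
        Path(path),
        data,
        metadata={
            "axes": "TZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
        ome=True,
    )


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def write_graph(graph: AJGraph, path: str | Path, spacing: tuple[float, float, float] | None = None) -> None:
    """Serialise an AJ graph as JSON.

    Positions are stored in micrometres (z, y, x); when ``spacing`` is given
    the equivalent 0-based voxel coordinates are stored alongside.
    """
    n = graph.n_vertices
    for u, v in graph.edges:
        if not (0 <= u < n and 0 <= v < n):  # pragma: no cover - ctor enforces
            raise ValueError(f"dangling edge ({u}, {v})")
    doc = {
        "type": "aj_graph",
        "vertices": [
            {
                "id": i,
                "position_um": [float(x) for x in graph.positions[i]],
                **(
                    {"position_voxel": [float(x) for x in graph.positions[i] / np.asarray(spacing)]}
                    if spacing
                    else {}
                ),
            }
            for i in range(n)
        ],
        "edges": [[int(u), int(v)] for u, v in graph.edges],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_graph(path: str | Path) -> AJGraph:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "aj_graph":
        raise ValueError(f"{path} is not an AJ graph document")
    verts = sorted(doc["vertices"], key=lambda v: v["id"])
    pos = np.array([v["position_um"] for v in verts]) if verts else np.empty((0, 3))
    return AJGraph(positions=pos, edges=[tuple(e) for e in doc["edges"]])


def write_cell_graph(cg: CellGraph, path: str | Path) -> None:
    doc = {
        "type": "cell_graph",
        "cells": [
            {
                "id": c.id,
                "boundary": [int(v) for v in c.boundary],
                "perimeter": c.perimeter,
                "area": c.area,
                "centroid_um": [float(x) for x in c.centroid],
                "width": c.width,
                "length": c.length,
                "rotation": c.rotation,
            }
            for c in cg.cells
        ],
        "edges": [[int(a), int(b)] for a, b in cg.edges],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_cell_graph(path: str | Path) -> CellGraph:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "cell_graph":
        raise ValueError(f"{path} is not a cell graph document")
    cells = [
        Cell(
            id=c["id"],
            boundary=list(c["boundary"]),
            perimeter=c["perimeter"],
            area=c["area"],
            centroid=np.array(c["centroid_um"]),
            width=c["width"],
            length=c["length"],
            rotation=c["rotation"],
        )
        for c in doc["cells"]
    ]
    return CellGraph(cells=cells, edges=[tuple(e) for e in doc["edges"]])


def write_graphml(graph: AJGraph, path: str | Path) -> None:
    """GraphML export (for inspection in external graph tools)."""
    import networkx as nx

    g = nx.Graph()
    for i in range(graph.n_vertices):
        z, y, x = graph.positions[i]
        g.add_node(i, z=float(z), y=float(y), x=float(x))
    g.add_edges_from(graph.edges)
    nx.write_graphml(g, Path(path))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def tracks_to_dataframe(
    tracks: list[CellTrack], cells_by_frame: list[dict[int, Cell]]
) -> pd.DataFrame:
    """Flatten tracks into a tidy table, one row per (track, frame).

    ``event`` marks the step where something happens: 'mitosis', 'apoptosis'
    or 'leaves' on a track's last row, 'enters' / 'mitosis-child' on a first
    row, else 'none'.
    """
    rows = []
    for tr in tracks:
        for k, (frame, cid) in enumerate(tr.steps):
            cell = cells_by_frame[frame][cid]
            event = "none"
            if k == len(tr.steps) - 1 and tr.terminal != "continues":
                event = tr.terminal
            elif k == 0 and tr.origin != "first-frame":
                event = tr.origin if tr.origin != "enters" else "enters"
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": frame,
                    "cell_id": cid,
                    "centroid_z": cell.centroid[0],
                    "centroid_y": cell.centroid[1],
                    "centroid_x": cell.centroid[2],
                    "area": cell.area,
                    "perimeter": cell.perimeter,
                    "width": cell.width,
                    "length": cell.length,
                    "rotation": cell.rotation,
                    "event": event,
                }
            )
    return pd.DataFrame(rows).sort_values(["track_id", "frame"]).reset_index(drop=True)
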