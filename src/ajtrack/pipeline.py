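"""Pipeline configuration and stage orchestration.

The stages mirror the analysis flow: (optionally) simulate, preprocess,
segment junctions into an AJ graph, identify cells as faces, track cells
across frames, smooth trajectories, and estimate per-frame strain-rate
tensors.  ``run_pipeline`` chains them deterministically from a single
config + seed and writes every artifact with the parameters echoed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .filters import ScaleSpaceParams, VertexDetectionParams, detect_vertices, plateness, vertexness
from .graphs import AJGraph, Cell, CellGraph, build_cell_graph, enumerate_faces
from .kinematics import KalmanModel, decompose_strain, fit_strain_rate, viterbi_smooth
from .marching import build_aj_graph, fast_march_supervertices, voronoi_labels
from .preprocess import DeconvolutionParams, PSFModel, clahe_3d, richardson_lucy_elasticnet
from .synthetic import RenderParams, TissueSimulationParams, generate_tissue_sequence, render_volume
from .tracker import (
    CellTrack,
    TrackerWeights,
    build_flow_network,
    link_tracks,
    solve_min_cost_flow,
)
from .volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "FilterConfig",
    "GraphConfig",
    "PipelineConfig",
    "load_config",
    "segment_volume",
    "prune_graph",
    "track_frames",
    "strain_table",
    "run_pipeline",
]


@dataclass
class PreprocessConfig:
    deconvolve: bool = False
    iterations: int = 20
    l1_weight: float = 0.01
    l2_weight: float = 0.0
    psf_widths: tuple[float, float, float] = (0.8, 0.15, 0.15)
    clahe: bool = True
    tile_shape: tuple[int, int, int] = (12, 33, 33)
    clip_limit: float = 0.02


@dataclass
class FilterConfig:
    sigma_min: float = 0.4
    sigma_max: float = 0.8
    n_scales: int = 3
    threshold: float = 0.2
    min_separation: float = 1.2  # um

    def scale_params(self) -> ScaleSpaceParams:
        return ScaleSpaceParams(self.sigma_min, self.sigma_max, self.n_scales)

    def detection_params(self) -> VertexDetectionParams:
        return VertexDetectionParams(self.threshold, self.min_separation)


@dataclass
class GraphConfig:
    t_threshold: float = 16.0  # supervertex travel-time budget T_E
    speed_floor: float = 1e-6  # F = P + V clipped below to stay positive

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")


@dataclass
class PipelineConfig:
    seed: int = 0
    input_path: str | None = None  # None -> simulate
    spacing_override: tuple[float, float, float] | None = None
    output_dir: str = "ajtrack_out"
    simulate: TissueSimulationParams = field(default_factory=TissueSimulationParams)
    render: RenderParams = field(default_factory=RenderParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    tracker: TrackerWeights = field(default_factory=TrackerWeights)
    kalman: KalmanModel = field(default_factory=KalmanModel)


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "simulate", "render", "preprocess", "filters", "graph", "tracker", "kalman",
        ):
            sub_cls = {
                "simulate": TissueSimulationParams,
                "render": RenderParams,
                "preprocess": PreprocessConfig,
                "filters": FilterConfig,
                "graph": GraphConfig,
                "tracker": TrackerWeights,
                "kalman": KalmanModel,
            }[f.name]
            v = _from_dict(sub_cls, v)
        elif isinstance(v, list):
            v = tuple(v) if f.name.endswith(("shape", "widths", "spacing", "override")) else np.asarray(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML pipeline configuration; unknown keys are rejected."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _from_dict(PipelineConfig, data)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def prune_graph(graph: AJGraph) -> AJGraph:
    """Trim an AJ graph for face enumeration.

    Keeps the largest connected component and iteratively removes dangling
    (degree <= 1) vertices, which cannot bound any cell.  Vertex positions
    are re-indexed; edges updated accordingly.
    """
    edges = set(graph.edges)
    alive = set(range(graph.n_vertices))
    while True:
        deg: dict[int, int] = {v: 0 for v in alive}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        drop = {v for v in alive if deg[v] <= 1}
        if not drop:
            break
        alive -= drop
        edges = {(u, v) for u, v in edges if u in alive and v in alive}
    # largest connected component
    adj: dict[int, list[int]] = {v: [] for v in alive}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen: set[int] = set()
    best: set[int] = set()
    for root in sorted(alive):
        if root in seen:
            continue
        comp = {root}
        stack = [root]
        while stack:
            w = stack.pop()
            for x in adj[w]:
                if x not in comp:
                    comp.add(x)
                    stack.append(x)
        seen |= comp
        if len(comp) > len(best):
            best = comp
    keep = sorted(best)
    remap = {old: new for new, old in enumerate(keep)}
    return AJGraph(
        positions=graph.positions[keep] if keep else np.empty((0, 3)),
        edges=sorted(
            (min(remap[u], remap[v]), max(remap[u], remap[v]))
            for u, v in edges
            if u in best and v in best
        ),
    )


def segment_volume(
    volume: ImageVolume,
    filters_cfg: FilterConfig,
    graph_cfg: GraphConfig,
    with_cells: bool = True,
) -> dict:
    """Segment one volume: filters -> vertices -> supervertices -> graphs.

    Returns a dict with the plateness/vertexness fields, detected vertex
    positions (um), the AJ graph and — when ``with_cells`` — the face-derived
    cells and dual cell graph.
    """
    scales = filters_cfg.scale_params()
    p_field = plateness(volume, scales)
    v_field = vertexness(volume, scales)
    verts = detect_vertices(v_field, volume.spacing, filters_cfg.detection_params())
    out = {"plateness": p_field, "vertexness": v_field, "vertices": verts}
    if verts.shape[0] < 2:
        out.update({"aj_graph": AJGraph(positions=verts, edges=[]), "cells": [],
                    "cell_graph": CellGraph(cells=[], edges=[])})
        return out
    speed = np.clip(p_field + v_field, graph_cfg.speed_floor, None)
    vor = voronoi_labels(verts, volume.shape, volume.spacing)
    super_labels, times = fast_march_supervertices(
        verts, speed, vor, volume.spacing, graph_cfg.t_threshold,
        init_radius=filters_cfg.min_separation / 2.0,
    )
    aj = build_aj_graph(super_labels, verts)
    out.update({"voronoi": vor, "supervertices": super_labels, "travel_times": times,
                "aj_graph": aj})
    if with_cells:
        pruned, faces = _faces_with_repair(prune_graph(aj))
        cg = build_cell_graph(faces, pruned)
        out.update({"aj_graph_pruned": pruned, "cells": cg.cells, "cell_graph": cg})
    return out


def _faces_with_repair(graph: AJGraph, max_repairs: int = 20) -> tuple[AJGraph, list[list[int]]]:
    """Enumerate faces, dropping embedding-breaking vertices if needed.

    Spurious detections inside cells can make the reconstructed graph
    non-embeddable; the face tracer reports the pinch vertices, which are
    removed (with re-pruning) and tracing retried.  Gives up after
    ``max_repairs`` rounds.
    """
    import re

    for _ in range(max_repairs):
        try:
            return graph, enumerate_faces(graph)
        except ValueError as exc:
            match = re.search(r"suspect vertices: \[([\d, ]*)\]", str(exc))
            suspects = [int(x) for x in match.group(1).split(",") if x.strip()] if match else []
            if not suspects:
                raise
            logger.info("face repair: removing %d pinch vertices", len(suspects))
            keep = [v for v in range(graph.n_vertices) if v not in set(suspects)]
            remap = {old: new for new, old in enumerate(keep)}
            graph = prune_graph(
                AJGraph(
                    positions=graph.positions[keep],
                    edges=sorted(
                        (min(remap[u], remap[v]), max(remap[u], remap[v]))
                        for u, v in graph.edges
                        if u in remap and v in remap
                    ),
                )
            )
    return graph, enumerate_faces(graph)


def _outer_boundary(graph: AJGraph) -> np.ndarray:
    """Positions of the outer face (max perimeter) of a pruned AJ graph."""
    faces = enumerate_faces(graph, drop_outer=False)
    perims = [
        sum(np.linalg.norm(graph.positions[f[(i + 1) % len(f)]] - graph.positions[f[i]])
            for i in range(len(f)))
        for f in faces
    ]
    return graph.positions[faces[int(np.argmax(perims))]]


def track_frames(
    cells_per_frame: list[list[Cell]],
    cell_graphs: list[CellGraph],
    boundaries: list[np.ndarray],
    positions_per_frame: list[np.ndarray],
    weights: TrackerWeights,
) -> tuple[list, list[CellTrack]]:
    """Solve every consecutive frame pair and stitch tracks."""
    solutions = []
    for t in range(len(cells_per_frame) - 1):
        net = build_flow_network(
            cells_per_frame[t],
            cells_per_frame[t + 1],
            cell_graphs[t + 1],
            positions_per_frame[t + 1],
            boundaries[t],
            boundaries[t + 1],
            weights,
        )
        sol = solve_min_cost_flow(net)
        logger.info(
            "frame pair %d->%d: %d hypotheses, %d selected", t, t + 1,
            len(net.hypotheses), len(sol),
        )
        solutions.append(sol)
    tracks = link_tracks(solutions, [[c.id for c in cs] for cs in cells_per_frame])
    return solutions, tracks


def strain_table(tracks_df: pd.DataFrame, model: KalmanModel | None = None) -> pd.DataFrame:
    """Smooth every track and fit a strain-rate tensor per frame.

    Input is the tidy tracks table (columns centroid_x/y, frame, track_id).
    Tracks shorter than 3 frames are excluded from the fit.  Returns one row
    per frame with the Jacobian entries, intercept, expansion and both
    rotation readouts.
    """
    model = model or KalmanModel()
    rows = []
    smoothed: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for tid, g in tracks_df.groupby("track_id"):
        g = g.sort_values("frame")
        if len(g) < 3:
            continue
        obs = g[["centroid_x", "centroid_y"]].to_numpy()
        states = viterbi_smooth(obs, model)
        smoothed[tid] = (g["frame"].to_numpy(), states)
    frames = sorted(tracks_df["frame"].unique())
    for fr in frames:
        pos, vel = [], []
        for frames_arr, states in smoothed.values():
            hit = np.nonzero(frames_arr == fr)[0]
            if hit.size:
                k = int(hit[0])
                pos.append(states[k, :2])
                vel.append(states[k, 2:])
        if len(pos) < 3:
            continue
        try:
            j, p0 = fit_strain_rate(np.array(pos), np.array(vel))
        except ValueError:
            continue
        sr = decompose_strain(j, p0)
        rows.append(
            {
                "frame": fr,
                "dxdot_dx": j[0, 0], "dxdot_dy": j[0, 1],
                "dydot_dx": j[1, 0], "dydot_dy": j[1, 1],
                "xdot0": p0[0], "ydot0": p0[1],
                "expansion": sr.expansion,
                "rotation_angle": sr.rotation_angle,
                "rotation_acos": sr.rotation_acos,
                "n_cells": len(pos),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write artifacts under ``config.output_dir``.

    Deterministic for a fixed config + seed.  Raises with the stage name and
    frame index on failure.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- input ------------------------------------------------------------
    if config.input_path is not None:
        volumes = aio.read_timelapse(config.input_path, config.spacing_override)
    else:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        sequence = generate_tissue_sequence(sim)
        rp = dataclasses.replace(config.render, seed=config.seed)
        volumes = [render_volume(f, rp) for f in sequence.frames]

    artifacts: dict[str, object] = {"volumes": volumes}
    all_cells: list[list[Cell]] = []
    cell_graphs: list[CellGraph] = []
    boundaries: list[np.ndarray] = []
    positions: list[np.ndarray] = []

    for t, vol in enumerate(volumes):
        try:
            if config.preprocess.deconvolve:
                vol = richardson_lucy_elasticnet(
                    vol,
                    PSFModel(widths=config.preprocess.psf_widths),
                    DeconvolutionParams(
                        iterations=config.preprocess.iterations,
                        l1_weight=config.preprocess.l1_weight,
                        l2_weight=config.preprocess.l2_weight,
                    ),
                )
            if config.preprocess.clahe:
                vol = clahe_3d(vol, config.preprocess.tile_shape, config.preprocess.clip_limit)
        except Exception as exc:
            raise RuntimeError(f"stage 'preprocess' failed at frame {t}: {exc}") from exc
        try:
            seg = segment_volume(vol, config.filters, config.graph)
        except Exception as exc:
            raise RuntimeError(f"stage 'segment' failed at frame {t}: {exc}") from exc
        pruned = seg.get("aj_graph_pruned", seg["aj_graph"])
        aio.write_graph(pruned, out_dir / f"aj_graph_t{t:03d}.json", spacing=vol.spacing)
        aio.write_cell_graph(seg["cell_graph"], out_dir / f"cell_graph_t{t:03d}.json")
        all_cells.append(seg["cells"])
        cell_graphs.append(seg["cell_graph"])
        positions.append(pruned.positions)
        try:
            boundaries.append(_outer_boundary(pruned))
        except Exception as exc:
            raise RuntimeError(f"stage 'cells' failed at frame {t}: {exc}") from exc

    try:
        solutions, tracks = track_frames(all_cells, cell_graphs, boundaries, positions,
                                         config.tracker)
    except Exception as exc:
        raise RuntimeError(f"stage 'track' failed: {exc}") from exc
    cells_by_frame = [{c.id: c for c in cs} for cs in all_cells]
    tracks_df = aio.tracks_to_dataframe(tracks, cells_by_frame)
    tracks_df.to_csv(out_dir / "tracks.csv", index=False)

    try:
        kin = strain_table(tracks_df, config.kalman)
    except Exception as exc:
        raise RuntimeError(f"stage 'strain' failed: {exc}") from exc
    kin.to_csv(out_dir / "kinematics.csv", index=False)

    (out_dir / "provenance.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "filters": dataclasses.asdict(config.filters),
                "graph": dataclasses.asdict(config.graph),
                "tracker": dataclasses.asdict(config.tracker),
            },
            indent=1,
        )
    )
    artifacts.update(
        {"cells": all_cells, "cell_graphs": cell_graphs, "tracks": tracks,
         "tracks_df": tracks_df, "kinematics": kin, "solutions": solutions,
         "output_dir": out_dir}
    )
    return artifacts
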