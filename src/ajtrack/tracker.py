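"""Frame-to-frame cell tracking with mitosis and apoptosis hypotheses.

Cell correspondence between consecutive frames is posed as a transportation
problem: every cell of frame ``t`` must be explained exactly once (matched to
a cell at ``t+1``, leaving the scene, or dying) and every cell of frame
``t+1`` must be explained exactly once (matched, entering, or born as one of
two mitosis siblings).  Hypotheses carry costs:

* association — a weighted sum of normalised differences between the two
  cells' polygon moments (centroid, area, perimeter, width, rotation,
  length);
* mitosis — the same moment distance between the parent and the *union
  polygon* of two sibling candidates, which must be adjacent in the
  ``t+1`` cell graph;
* enter / leave — proportional to the centroid's distance to the tissue
  boundary (cells can only plausibly appear or disappear near the edge of
  the imaged field);
* apoptosis — proportional to the dying cell's area (apoptotic cells shrink
  before they vanish).

The method has 11 parameters: 6 feature weights and 5 hypothesis weights.
Feature differences are normalised by a robust per-frame-pair scale (median
absolute difference over candidate pairs) so the weights are dimensionless.
The coupled selection is solved exactly as an integer program (costs rounded
to 1e-6 resolution; deterministic tie-break preferring lower hypothesis
ids), which a brute-force enumeration oracle verifies on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix

from .graphs import Cell, CellGraph, polygon_moments, union_boundary

__all__ = [
    "TrackerWeights",
    "FeatureScales",
    "Hypothesis",
    "FlowNetwork",
    "CellTrack",
    "moment_distance",
    "association_cost",
    "mitosis_cost",
    "boundary_costs",
    "apoptosis_cost",
    "compute_feature_scales",
    "build_flow_network",
    "solve_min_cost_flow",
    "link_tracks",
    "distance_to_boundary",
]


@dataclass
class TrackerWeights:
    """The 11 tracking parameters: 6 feature + 5 hypothesis weights."""

    centroid: float = 16.0
    area: float = 0.5
    perimeter: float = 0.5
    width: float = 0.25
    rotation: float = 0.25
    length: float = 0.25
    association: float = 1.0  # additive offset per association
    enter: float = 2.0  # per um of centroid-to-boundary distance
    mitosis: float = 8.0  # additive offset per mitosis
    apoptosis: float = 0.5  # per um^2 of dying-cell area
    leave: float = 2.0  # per um of centroid-to-boundary distance

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"weight {name} must be >= 0")


@dataclass
class FeatureScales:
    """Robust normalisation scales for the 6 moment features."""

    centroid: float = 1.0
    area: float = 1.0
    perimeter: float = 1.0
    width: float = 1.0
    rotation: float = 1.0
    length: float = 1.0


@dataclass
class Hypothesis:
    kind: str  # association | enter | leave | mitosis | apoptosis
    source: int | None  # cell id in frame t
    targets: tuple[int, ...]  # cell ids in frame t+1
    cost: float


@dataclass
class FlowNetwork:
    """Coupled hypothesis network for one frame pair.

    ``n + m`` units of flow (one per cell on either side) must be routed so
    that each frame-t cell and each frame-(t+1) cell is covered exactly once.
    """

    cells_t: list[int]
    cells_t1: list[int]
    hypotheses: list[Hypothesis] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.cells_t)

    @property
    def m(self) -> int:
        return len(self.cells_t1)


@dataclass
class CellTrack:
    track_id: int
    steps: list[tuple[int, int]]  # (frame, cell id)
    origin: str = "first-frame"  # first-frame | enters | mitosis-child
    parent_track: int | None = None
    terminal: str = "continues"  # continues | leaves | apoptosis | mitosis
    children: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------


def _rotation_distance(r1: float, r2: float) -> float:
    """Angle between two unsigned elongation axes, in [0, pi/2]."""
    d = abs(r1 - r2) % np.pi
    return min(d, np.pi - d)


def moment_distance(
    c1: Cell | dict, c2: Cell | dict, weights: TrackerWeights, scales: FeatureScales
) -> float:
    """Weighted sum of normalised absolute moment differences."""

    def get(c, name):
        return c[name] if isinstance(c, dict) else getattr(c, name)

    d = 0.0
    d += weights.centroid * float(
        np.linalg.norm(np.asarray(get(c1, "centroid")) - np.asarray(get(c2, "centroid")))
    ) / scales.centroid
    d += weights.area * abs(get(c1, "area") - get(c2, "area")) / scales.area
    d += weights.perimeter * abs(get(c1, "perimeter") - get(c2, "perimeter")) / scales.perimeter
    d += weights.width * abs(get(c1, "width") - get(c2, "width")) / scales.width
    d += weights.rotation * _rotation_distance(get(c1, "rotation"), get(c2, "rotation")) / scales.rotation
    d += weights.length * abs(get(c1, "length") - get(c2, "length")) / scales.length
    return d


def association_cost(
    cell_t: Cell, cell_t1: Cell, weights: TrackerWeights, scales: FeatureScales | None = None
) -> float:
    scales = scales or FeatureScales()
    return weights.association + moment_distance(cell_t, cell_t1, weights, scales)


def mitosis_cost(
    parent: Cell,
    child1: Cell,
    child2: Cell,
    cell_graph_t1: CellGraph,
    positions_t1: np.ndarray,
    weights: TrackerWeights,
    scales: FeatureScales | None = None,
) -> float | None:
    """Cost of ``parent`` dividing into two adjacent siblings, or None.

    Non-adjacent sibling pairs generate no hypothesis.  The moment distance
    is taken between the parent and the merged polygon of the two children
    (shared AJ edges deleted, combined boundary re-traced).
    """
    if not cell_graph_t1.are_adjacent(child1.id, child2.id):
        return None
    ring = union_boundary(child1.boundary, child2.boundary)
    if ring is None:
        return None
    scales = scales or FeatureScales()
    try:
        union_m = polygon_moments(positions_t1[ring])
    except ValueError:
        return None
    return weights.mitosis + moment_distance(parent, union_m, weights, scales)


def distance_to_boundary(point: np.ndarray, boundary: np.ndarray) -> float:
    """Distance from a 3D point to a closed polyline (nearest segment)."""
    p = np.asarray(point, dtype=float)
    b = np.asarray(boundary, dtype=float)
    k = b.shape[0]
    best = np.inf
    for i in range(k):
        a, c = b[i], b[(i + 1) % k]
        ac = c - a
        denom = float(ac @ ac)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ac / denom, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(p - (a + t * ac))))
    return best


def boundary_costs(
    cell: Cell, tissue_boundary: np.ndarray, weights: TrackerWeights
) -> tuple[float, float]:
    """(enter, leave) costs: hypothesis weight x distance to the scene edge."""
    d = distance_to_boundary(cell.centroid, tissue_boundary)
    return weights.enter * d, weights.leave * d


def apoptosis_cost(cell: Cell, weights: TrackerWeights) -> float:
    return weights.apoptosis * cell.area


def compute_feature_scales(
    cells_t: list[Cell], cells_t1: list[Cell], candidates: list[tuple[int, int]]
) -> FeatureScales:
    """Median absolute feature difference over candidate association pairs.

    Scales are floored at a small fraction of the feature's typical size so
    that a frame pair of identical cells does not divide by zero.
    """
    by_id_t = {c.id: c for c in cells_t}
    by_id_t1 = {c.id: c for c in cells_t1}
    diffs: dict[str, list[float]] = {k: [] for k in
                                     ("centroid", "area", "perimeter", "width", "rotation", "length")}
    for i, j in candidates:
        a, b = by_id_t[i], by_id_t1[j]
        diffs["centroid"].append(float(np.linalg.norm(a.centroid - b.centroid)))
        diffs["area"].append(abs(a.area - b.area))
        diffs["perimeter"].append(abs(a.perimeter - b.perimeter))
        diffs["width"].append(abs(a.width - b.width))
        diffs["rotation"].append(_rotation_distance(a.rotation, b.rotation))
        diffs["length"].append(abs(a.length - b.length))
    typical = {
        "centroid": float(np.median([c.length for c in cells_t])) or 1.0,
        "area": float(np.median([c.area for c in cells_t])) or 1.0,
        "perimeter": float(np.median([c.perimeter for c in cells_t])) or 1.0,
        "width": float(np.median([c.width for c in cells_t])) or 1.0,
        "rotation": np.pi / 2,
        "length": float(np.median([c.length for c in cells_t])) or 1.0,
    }
    out = {}
    for k, vals in diffs.items():
        med = float(np.median(vals)) if vals else 0.0
        out[k] = max(med, 0.05 * typical[k], 1e-9)
    return FeatureScales(**out)


# ---------------------------------------------------------------------------
# network construction and exact solve
# ---------------------------------------------------------------------------


def build_flow_network(
    cells_t: list[Cell],
    cells_t1: list[Cell],
    cell_graph_t1: CellGraph,
    positions_t1: np.ndarray,
    boundary_t: np.ndarray,
    boundary_t1: np.ndarray,
    weights: TrackerWeights,
    gating_radius: float | None = None,
) -> FlowNetwork:
    """Generate all hypotheses for one frame pair.

    Association candidates are gated to pairs whose centroid distance is
    below ``gating_radius`` (default: 3x the median cell diameter), standing
    in for the adjacency restriction of cells embedded in a sheet; mitosis
    sibling pairs must additionally be adjacent in the t+1 cell graph.
    Enter/leave/apoptosis hypotheses always exist, so the network is feasible.
    """
    if not cells_t or not cells_t1:
        raise ValueError("both frames must contain at least one cell")
    if gating_radius is None:
        diam = np.median([2.0 * np.sqrt(c.area / np.pi) for c in cells_t + cells_t1])
        gating_radius = 3.0 * float(diam)

    candidates = [
        (a.id, b.id)
        for a in cells_t
        for b in cells_t1
        if np.linalg.norm(a.centroid - b.centroid) <= gating_radius
    ]
    scales = compute_feature_scales(cells_t, cells_t1, candidates)
    by_id_t1 = {c.id: c for c in cells_t1}

    net = FlowNetwork(cells_t=[c.id for c in cells_t], cells_t1=[c.id for c in cells_t1])
    by_id_t = {c.id: c for c in cells_t}
    for i, j in candidates:
        net.hypotheses.append(
            Hypothesis("association", i, (j,),
                       association_cost(by_id_t[i], by_id_t1[j], weights, scales))
        )
    for a in cells_t:
        for j, k in cell_graph_t1.edges:
            c1, c2 = by_id_t1[j], by_id_t1[k]
            if (
                np.linalg.norm(a.centroid - c1.centroid) > gating_radius
                or np.linalg.norm(a.centroid - c2.centroid) > gating_radius
            ):
                continue
            cost = mitosis_cost(a, c1, c2, cell_graph_t1, positions_t1, weights, scales)
            if cost is not None:
                net.hypotheses.append(Hypothesis("mitosis", a.id, (j, k), cost))
    for a in cells_t:
        _, leave = boundary_costs(a, boundary_t, weights)
        net.hypotheses.append(Hypothesis("leave", a.id, (), leave))
        net.hypotheses.append(Hypothesis("apoptosis", a.id, (), apoptosis_cost(a, weights)))
    for b in cells_t1:
        enter, _ = boundary_costs(b, boundary_t1, weights)
        net.hypotheses.append(Hypothesis("enter", None, (b.id,), enter))
    return net


def solve_min_cost_flow(network: FlowNetwork) -> list[Hypothesis]:
    """Exact minimum-cost coupled selection of hypotheses.

    Each frame-t cell and each frame-(t+1) cell must be covered by exactly
    one selected hypothesis.  Costs are rounded to 1e-6 resolution; among
    cost ties the selection with lower hypothesis ids is preferred (via an
    infinitesimal lexicographic perturbation), making the result
    deterministic.
    """
    hyps = network.hypotheses
    n_h = len(hyps)
    if n_h == 0:
        raise ValueError("empty hypothesis set")
    left_index = {cid: r for r, cid in enumerate(network.cells_t)}
    right_index = {cid: r for r, cid in enumerate(network.cells_t1)}
    n_rows = len(left_index) + len(right_index)
    a = lil_matrix((n_rows, n_h))
    for h_idx, h in enumerate(hyps):
        if h.source is not None:
            a[left_index[h.source], h_idx] = 1
        for t in h.targets:
            a[len(left_index) + right_index[t], h_idx] = 1
    cost_int = np.round(np.array([h.cost for h in hyps]) / 1e-6)
    tie = (np.arange(n_h) + 1) / (2.0 * n_h * (n_h + 1))  # total always < 1
    c = cost_int + tie
    res = milp(
        c=c,
        constraints=LinearConstraint(a.tocsr(), lb=np.ones(n_rows), ub=np.ones(n_rows)),
        integrality=np.ones(n_h),
        bounds=(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"coupled assignment infeasible: {res.message}")
    chosen = [hyps[i] for i in range(n_h) if res.x[i] > 0.5]
    _check_conservation(network, chosen)
    return chosen


def _check_conservation(network: FlowNetwork, chosen: list[Hypothesis]) -> None:
    counts = {k: 0 for k in ("association", "enter", "leave", "mitosis", "apoptosis")}
    for h in chosen:
        counts[h.kind] += 1
    n_explained = counts["association"] + counts["leave"] + counts["apoptosis"] + counts["mitosis"]
    m_explained = counts["association"] + counts["enter"] + 2 * counts["mitosis"]
    if n_explained != network.n or m_explained != network.m:
        raise RuntimeError(
            f"conservation violated: N={network.n} explained {n_explained}, "
            f"M={network.m} explained {m_explained}"
        )


# ---------------------------------------------------------------------------
# track linking
# ---------------------------------------------------------------------------


def link_tracks(
    solutions: list[list[Hypothesis]], cells_per_frame: list[list[int]]
) -> list[CellTrack]:
    """Stitch per-frame-pair solutions into whole-sequence cell tracks.

    ``solutions[t]`` explains the transition from frame ``t`` to ``t+1``;
    ``cells_per_frame[t]`` lists the cell ids present in frame ``t``.  Every
    cell of every frame ends up in exactly one track; mitosis records the
    lineage (parent track -> two child tracks).
    """
    tracks: list[CellTrack] = []
    active: dict[int, int] = {}  # cell id in current frame -> track id

    def new_track(frame: int, cell_id: int, origin: str, parent: int | None = None) -> int:
        tid = len(tracks)
        tracks.append(CellTrack(track_id=tid, steps=[(frame, cell_id)], origin=origin,
                                parent_track=parent))
        return tid

    for cid in cells_per_frame[0]:
        active[cid] = new_track(0, cid, "first-frame")

    for t, sol in enumerate(solutions):
        next_active: dict[int, int] = {}
        covered_left: set[int] = set()
        for h in sol:
            if h.source is not None:
                if h.source in covered_left:
                    raise ValueError(f"cell {h.source} claimed twice in frame {t}")
                covered_left.add(h.source)
            if h.kind == "association":
                tid = active[h.source]
                tracks[tid].steps.append((t + 1, h.targets[0]))
                next_active[h.targets[0]] = tid
            elif h.kind == "enter":
                next_active[h.targets[0]] = new_track(t + 1, h.targets[0], "enters")
            elif h.kind == "leave":
                tracks[active[h.source]].terminal = "leaves"
            elif h.kind == "apoptosis":
                tracks[active[h.source]].terminal = "apoptosis"
            elif h.kind == "mitosis":
                ptid = active[h.source]
                ch = tuple(
                    new_track(t + 1, tgt, "mitosis-child", parent=ptid) for tgt in h.targets
                )
                tracks[ptid].terminal = "mitosis"
                tracks[ptid].children = ch
                for tgt, tid in zip(h.targets, ch):
                    next_active[tgt] = tid
        expected = set(cells_per_frame[t + 1])
        if set(next_active) != expected:
            missing = expected - set(next_active)
            extra = set(next_active) - expected
            raise ValueError(
                f"frame {t + 1} partition broken (missing {sorted(missing)[:5]}, "
                f"extra {sorted(extra)[:5]})"
            )
        active = next_active
    return tracks
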