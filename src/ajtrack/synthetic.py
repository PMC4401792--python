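"""Synthetic epithelial tissue with ground truth, and volume rendering.

Every pipeline stage is testable without real data: the generator produces a
planar (or tube-wrapped) cell packing with known vertices, edges, cells,
tracks and lineage events, and the renderer turns any frame into a confocal-
like 3D stack with the characteristic nuisances of junctional imaging —
uneven belt intensity with gaps, bright vesicle clutter, very bright
bristle cells, anisotropic PSF blur and Poisson photon noise.

The initial packing is a centroidal Voronoi tessellation (a few Lloyd
relaxation steps), which resembles the mildly disordered polygonal packing
of a real epithelium.  Dynamics are prescribed, not mechanical: vertices are
advected by an affine velocity field (the ground-truth strain rate) plus
jitter; a mitosis splits a face along its short axis (inserting two new
vertices and a junction, which makes the two children adjacent); an
apoptosis shrinks a face towards its centroid over two frames and then
collapses it to a single vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi

from .graphs import AJGraph, Cell, CellGraph, polygon_moments
from .tracker import Hypothesis
from .volume import ImageVolume

__all__ = [
    "TissueSimulationParams",
    "RenderParams",
    "TissueFrame",
    "TissueSequence",
    "generate_tissue_sequence",
    "render_volume",
    "corrupt_tracks",
]


@dataclass
class TissueSimulationParams:
    """Study conditions for the simulated tissue.

    Defaults describe the standard scenario used throughout the test suite:
    a 50-cell planar patch followed for 10 frames under a gentle affine
    drift (slight expansion plus rotation, as a developing epithelium shows
    between 10-minute frames), with 3 mitoses and 2 apoptoses.
    """

    geometry: str = "planar"  # planar | tube
    n_cells: int = 50
    n_frames: int = 10
    domain_size: float = 30.0  # um
    jacobian: np.ndarray = field(
        default_factory=lambda: np.array([[0.008, 0.004], [-0.004, 0.006]])
    )  # per frame
    drift: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.15]))  # um/frame
    n_mitosis: int = 3
    n_apoptosis: int = 2
    mitosis_prob: float = 0.0  # per cell per frame, used when n_mitosis is None
    apoptosis_prob: float = 0.0
    jitter: float = 0.05  # um of per-vertex positional noise per frame
    height_amplitude: float = 0.8  # um of apical-surface curvature
    lloyd_iterations: int = 4
    min_edge_length: float = 0.4  # um; shorter junction edges are contracted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("planar", "tube"):
            raise ValueError("geometry must be 'planar' or 'tube'")
        if not (0 <= self.mitosis_prob <= 1 and 0 <= self.apoptosis_prob <= 1):
            raise ValueError("event probabilities must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)


@dataclass
class RenderParams:
    """Imaging model for turning ground-truth geometry into a stack."""

    spacing: tuple[float, float, float] = (0.6, 0.25, 0.25)  # um (z, y, x)
    margin: float = 1.5  # um of empty border around the tissue
    apical_z: float = 2.0  # um depth of the apical surface
    belt_height: float = 1.0  # um of junctional wall below the apical surface
    junction_intensity: float = 1.0
    unevenness: float = 0.3  # log-scale per-edge intensity spread
    gap_probability: float = 0.1  # per edge
    gap_fraction: float = 0.25  # length fraction removed by a gap
    vesicle_density: float = 0.02  # puncta per um^3 below the belt
    vesicle_brightness: float = 1.5
    bristle_probability: float = 0.02  # per cell
    bristle_multiplier: float = 3.0
    psf_widths: tuple[float, float, float] = (0.5, 0.12, 0.12)  # um
    photon_scale: float = 200.0  # photons per intensity unit; 0 = no signal
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.photon_scale < 0 or self.vesicle_density < 0:
            raise ValueError("render parameters must be non-negative")


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------


@dataclass
class TissueFrame:
    """Ground-truth geometry of one time point.

    ``vertex_pos`` maps vertex id -> (x, y) in um; ``cells`` maps a
    *persistent* cell id -> ordered ring of vertex ids.  Heights (z) come
    from the sequence's surface function when 3D positions are requested.
    """

    index: int
    vertex_pos: dict[int, np.ndarray]
    cells: dict[int, list[int]]
    domain_size: float
    height_amplitude: float = 0.0
    geometry: str = "planar"

    def _height(self, x: float, y: float) -> float:
        l = self.domain_size
        return self.height_amplitude * float(
            np.sin(2 * np.pi * x / l) * np.cos(2 * np.pi * y / l)
        )

    def position3d(self, vid: int) -> np.ndarray:
        """(z, y, x) micrometre position of a vertex."""
        x, y = self.vertex_pos[vid]
        if self.geometry == "tube":
            r = self.domain_size / (2 * np.pi)
            theta = 2 * np.pi * x / self.domain_size
            return np.array([r + r * np.cos(theta), y, r + r * np.sin(theta)])
        return np.array([self._height(x, y), y, x])

    def aj_graph(self) -> tuple[AJGraph, dict[int, int]]:
        """AJ graph of this frame plus the vertex-id -> index mapping."""
        vids = sorted(self.vertex_pos)
        index = {vid: i for i, vid in enumerate(vids)}
        pos = np.array([self.position3d(v) for v in vids])
        edges = set()
        for ring in self.cells.values():
            for i, u in enumerate(ring):
                v = ring[(i + 1) % len(ring)]
                edges.add((min(index[u], index[v]), max(index[u], index[v])))
        return AJGraph(positions=pos, edges=sorted(edges)), index

    def cell_objects(self) -> tuple[list[Cell], CellGraph, np.ndarray]:
        """Cells with moments, the (ground-truth) dual graph, and positions.

        Cell ids are the persistent simulation ids.  The dual edge set joins
        cells sharing at least one junction edge, exactly as the dual of the
        face set would.
        """
        graph, index = self.aj_graph()
        cells = []
        edge_to_cells: dict[tuple[int, int], list[int]] = {}
        for cid, ring in sorted(self.cells.items()):
            ring_idx = [index[v] for v in ring]
            m = polygon_moments(graph.positions[ring_idx])
            cells.append(
                Cell(id=cid, boundary=ring_idx, perimeter=m["perimeter"], area=m["area"],
                     centroid=m["centroid"], width=m["width"], length=m["length"],
                     rotation=m["rotation"])
            )
            for i, u in enumerate(ring_idx):
                v = ring_idx[(i + 1) % len(ring_idx)]
                edge_to_cells.setdefault((min(u, v), max(u, v)), []).append(cid)
        dual = sorted(
            {(min(a, b), max(a, b)) for cs in edge_to_cells.values() if len(cs) == 2
             for a, b in [cs]}
        )
        return cells, CellGraph(cells=cells, edges=dual), graph.positions

    def boundary_ring(self) -> np.ndarray:
        """3D positions of the outer tissue boundary (closed walk)."""
        edge_count: dict[tuple[int, int], int] = {}
        for ring in self.cells.values():
            for i, u in enumerate(ring):
                v = ring[(i + 1) % len(ring)]
                e = (min(u, v), max(u, v))
                edge_count[e] = edge_count.get(e, 0) + 1
        border = [e for e, c in edge_count.items() if c == 1]
        adj: dict[int, list[int]] = {}
        for u, v in border:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        start = min(adj)
        walk = [start]
        prev, cur = None, start
        while True:
            nxts = [w for w in adj[cur] if w != prev]
            nxt = nxts[0] if nxts else prev
            if nxt == start:
                break
            walk.append(nxt)
            prev, cur = cur, nxt
        return np.array([self.position3d(v) for v in walk])


@dataclass
class TissueSequence:
    """A simulated time lapse with complete ground truth."""

    params: TissueSimulationParams
    frames: list[TissueFrame]
    true_solutions: list[list[Hypothesis]]  # per frame pair
    events: list[dict]  # {frame, kind, parent, children}

    def cells_per_frame(self) -> list[list[int]]:
        return [sorted(f.cells) for f in self.frames]


# ---------------------------------------------------------------------------
# initial packing
# ---------------------------------------------------------------------------


def _centroidal_voronoi(
    n: int, size: float, iterations: int, rng: np.random.Generator,
    min_edge: float = 0.4,
) -> tuple[dict[int, np.ndarray], dict[int, list[int]]]:
    """Lloyd-relaxed bounded Voronoi packing on [0, size]^2."""
    pts = rng.uniform(0.12 * size, 0.88 * size, size=(n, 2))

    def mirrored(p: np.ndarray) -> np.ndarray:
        left = p.copy(); left[:, 0] = -left[:, 0]
        right = p.copy(); right[:, 0] = 2 * size - right[:, 0]
        down = p.copy(); down[:, 1] = -down[:, 1]
        up = p.copy(); up[:, 1] = 2 * size - up[:, 1]
        return np.vstack([p, left, right, down, up])

    for _ in range(iterations):
        vor = Voronoi(mirrored(pts))
        new = pts.copy()
        for i in range(n):
            region = vor.regions[vor.point_region[i]]
            poly = vor.vertices[region]
            x, y = poly[:, 0], poly[:, 1]
            x1, y1 = np.roll(x, -1), np.roll(y, -1)
            cross = x * y1 - x1 * y
            area = 0.5 * cross.sum()
            if abs(area) > 1e-12:
                new[i, 0] = ((x + x1) * cross).sum() / (6 * area)
                new[i, 1] = ((y + y1) * cross).sum() / (6 * area)
        pts = new

    vor = Voronoi(mirrored(pts))
    vertex_pos: dict[int, np.ndarray] = {}
    remap: dict[int, int] = {}
    cells: dict[int, list[int]] = {}
    next_vid = 0
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        ring = []
        for vi in region:
            if vi not in remap:
                remap[vi] = next_vid
                vertex_pos[next_vid] = vor.vertices[vi].copy()
                next_vid += 1
            ring.append(remap[vi])
        cells[i] = ring

    _contract_short_edges(vertex_pos, cells, min_edge)
    return vertex_pos, cells


def _contract_short_edges(
    vertex_pos: dict[int, np.ndarray], cells: dict[int, list[int]], min_len: float
) -> None:
    """Merge endpoints of junction edges shorter than ``min_len``.

    Random Voronoi diagrams contain arbitrarily short edges; under per-frame
    vertex jitter these can flip and self-intersect a cell.  Contracting them
    yields occasional higher-degree vertices (four-cell rosettes), which real
    epithelia show as well.
    """
    while True:
        shortest = None
        for ring in cells.values():
            for i, u in enumerate(ring):
                v = ring[(i + 1) % len(ring)]
                d = float(np.linalg.norm(vertex_pos[u] - vertex_pos[v]))
                if d < min_len and (shortest is None or d < shortest[0]):
                    shortest = (d, u, v)
        if shortest is None:
            return
        _, u, v = shortest
        vertex_pos[u] = 0.5 * (vertex_pos[u] + vertex_pos[v])
        del vertex_pos[v]
        for cid, ring in list(cells.items()):
            new = [u if w == v else w for w in ring]
            dedup = [w for i, w in enumerate(new) if w != new[(i + 1) % len(new)]]
            if len(dedup) < 3:
                raise ValueError("edge contraction degenerated a cell; lower min_edge_length")
            cells[cid] = dedup


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def _edge_cell_map(cells: dict[int, list[int]]) -> dict[tuple[int, int], list[int]]:
    out: dict[tuple[int, int], list[int]] = {}
    for cid, ring in cells.items():
        for i, u in enumerate(ring):
            v = ring[(i + 1) % len(ring)]
            out.setdefault((min(u, v), max(u, v)), []).append(cid)
    return out


def _interior_cells(cells: dict[int, list[int]]) -> list[int]:
    ecm = _edge_cell_map(cells)
    border_cells = {cs[0] for e, cs in ecm.items() if len(cs) == 1}
    return sorted(set(cells) - border_cells)


def _insert_vertex_on_edge(cells: dict[int, list[int]], u: int, v: int, w: int) -> None:
    for ring in cells.values():
        k = len(ring)
        for i in range(k):
            a, b = ring[i], ring[(i + 1) % k]
            if {a, b} == {u, v}:
                ring.insert(i + 1, w)
                break


def _ring_moments_2d(ring: list[int], vertex_pos: dict[int, np.ndarray]) -> dict:
    pts = np.array([[0.0, p[1], p[0]] for p in (vertex_pos[v] for v in ring)])
    return polygon_moments(pts)


def _split_cell(
    frame_cells: dict[int, list[int]],
    vertex_pos: dict[int, np.ndarray],
    cid: int,
    next_vid: int,
    next_cid: int,
) -> tuple[int, int, int, int] | None:
    """Split cell ``cid`` along its short axis.  Returns (c1, c2, vid, cid)."""
    ring = frame_cells[cid]
    m = _ring_moments_2d(ring, vertex_pos)
    c = np.array([m["centroid"][2], m["centroid"][1]])  # (x, y)
    r = m["rotation"]
    major = np.array([np.cos(r), np.sin(r)])
    hits: list[tuple[int, float]] = []
    k = len(ring)
    for i in range(k):
        a = vertex_pos[ring[i]]
        b = vertex_pos[ring[(i + 1) % k]]
        denom = float((b - a) @ major)
        if abs(denom) < 1e-12:
            continue
        u = float((c - a) @ major) / denom
        seg = float(np.linalg.norm(b - a))
        if 0.0 < u < 1.0 and min(u, 1 - u) * seg >= 0.3:
            hits.append((i, u))
    if len(hits) != 2:
        return None
    (i1, u1), (i2, u2) = hits
    w1 = next_vid
    w2 = next_vid + 1
    p1 = vertex_pos[ring[i1]] + u1 * (vertex_pos[ring[(i1 + 1) % k]] - vertex_pos[ring[i1]])
    p2 = vertex_pos[ring[i2]] + u2 * (vertex_pos[ring[(i2 + 1) % k]] - vertex_pos[ring[i2]])
    vertex_pos[w1] = p1
    vertex_pos[w2] = p2
    # insert the new vertices into every ring sharing the split edges
    e1 = (ring[i1], ring[(i1 + 1) % k])
    e2 = (ring[i2], ring[(i2 + 1) % k])
    _insert_vertex_on_edge(frame_cells, *e1, w1)
    _insert_vertex_on_edge(frame_cells, *e2, w2)
    ring = frame_cells[cid]  # now contains w1 and w2
    j1, j2 = ring.index(w1), ring.index(w2)
    if j1 > j2:
        j1, j2 = j2, j1
        w1, w2 = w2, w1
    child1 = ring[j1 : j2 + 1]  # w1 ... w2
    child2 = ring[j2:] + ring[: j1 + 1]  # w2 ... w1
    if len(child1) < 3 or len(child2) < 3:
        return None
    c1, c2 = next_cid, next_cid + 1
    del frame_cells[cid]
    frame_cells[c1] = child1
    frame_cells[c2] = child2
    return c1, c2, next_vid + 2, next_cid + 2


def _collapse_cell(
    frame_cells: dict[int, list[int]],
    vertex_pos: dict[int, np.ndarray],
    cid: int,
    next_vid: int,
) -> int | None:
    """Remove cell ``cid`` by collapsing its ring to a single vertex."""
    ring = frame_cells[cid]
    dying = set(ring)
    centroid = np.mean([vertex_pos[v] for v in ring], axis=0)
    # check every other ring holds at most one contiguous run of dying vertices
    replacements: dict[int, list[int]] = {}
    for ocid, oring in frame_cells.items():
        if ocid == cid:
            continue
        flags = [v in dying for v in oring]
        if not any(flags):
            continue
        runs = sum(
            1 for i in range(len(oring)) if flags[i] and not flags[i - 1]
        )
        if runs != 1:
            return None
        new_ring = [v for v in oring if v not in dying]
        if len(new_ring) < 2:
            return None
        # insert the collapse vertex where the run was
        k = len(oring)
        start = next(i for i in range(k) if flags[i] and not flags[i - 1])
        anchor = oring[start - 1]
        pos = new_ring.index(anchor) + 1
        candidate = new_ring[:pos] + [next_vid] + new_ring[pos:]
        if len(candidate) < 3:
            return None
        replacements[ocid] = candidate
    vertex_pos[next_vid] = centroid
    for ocid, new_ring in replacements.items():
        frame_cells[ocid] = new_ring
    del frame_cells[cid]
    for v in dying:
        if not any(v in r for r in frame_cells.values()):
            del vertex_pos[v]
    return next_vid + 1


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def generate_tissue_sequence(params: TissueSimulationParams | None = None) -> TissueSequence:
    """Simulate a tissue time lapse with complete ground truth.

    Frame 0 is a centroidal-Voronoi packing; each transition advects all
    vertices by the affine field plus jitter and applies any scheduled
    events.  Mitoses are scheduled at evenly spread transitions; each
    apoptosis shrinks its cell for one frame before the collapse.  The
    ground-truth hypothesis list of every frame pair (associations, mitoses,
    apoptoses) is recorded alongside.
    """
    params = params or TissueSimulationParams()
    rng = np.random.default_rng(params.seed)
    vertex_pos, cells = _centroidal_voronoi(
        params.n_cells, params.domain_size, params.lloyd_iterations, rng,
        min_edge=params.min_edge_length,
    )
    next_vid = max(vertex_pos) + 1
    next_cid = max(cells) + 1

    t_count = params.n_frames
    # schedule events on transitions 1 .. t_count-2 (events need stable frames
    # on both sides); apoptoses claim two consecutive transitions
    mito_frames: list[int] = []
    apo_frames: list[int] = []
    usable = max(t_count - 2, 1)
    if params.n_mitosis:
        mito_frames = [1 + (i * usable) // params.n_mitosis for i in range(params.n_mitosis)]
    if params.n_apoptosis:
        apo_frames = [
            min(max(1, (i + 1) * usable // (params.n_apoptosis + 1)), max(t_count - 4, 1))
            for i in range(params.n_apoptosis)
        ]

    frames: list[TissueFrame] = []
    true_solutions: list[list[Hypothesis]] = []
    events: list[dict] = []
    shrinking: dict[int, int] = {}  # cell id -> transitions left before collapse

    def snapshot(idx: int) -> TissueFrame:
        return TissueFrame(
            index=idx,
            vertex_pos={v: p.copy() for v, p in vertex_pos.items()},
            cells={c: list(r) for c, r in cells.items()},
            domain_size=params.domain_size,
            height_amplitude=params.height_amplitude,
            geometry=params.geometry,
        )

    frames.append(snapshot(0))
    center = np.array([params.domain_size / 2, params.domain_size / 2])

    for t in range(t_count - 1):
        prev_ids = set(cells)
        sol: list[Hypothesis] = []

        # advect vertices by the affine field (about the domain centre)
        for v in list(vertex_pos):
            p = vertex_pos[v]
            vel = params.jacobian @ (p - center) + params.drift
            vertex_pos[v] = p + vel + rng.normal(0.0, params.jitter, size=2)

        # collapses that finished shrinking on earlier transitions
        for cid in [c for c, left in shrinking.items() if left <= 0]:
            res = _collapse_cell(cells, vertex_pos, cid, next_vid)
            if res is None:
                continue  # retry next transition
            next_vid = res
            del shrinking[cid]
            sol.append(Hypothesis("apoptosis", cid, (), 0.0))
            events.append({"frame": t + 1, "kind": "apoptosis", "parent": cid, "children": ()})

        # shrink dying cells towards their centroid (visible for two frames)
        for cid in list(shrinking):
            ring = cells.get(cid)
            if ring is None:
                del shrinking[cid]
                continue
            centroid = np.mean([vertex_pos[v] for v in ring], axis=0)
            for v in ring:
                vertex_pos[v] = centroid + 0.45 * (vertex_pos[v] - centroid)
            shrinking[cid] -= 1

        # scheduled mitoses on this transition
        n_mito_here = mito_frames.count(t + 1)
        if params.n_mitosis == 0 and params.mitosis_prob > 0:
            n_mito_here = rng.binomial(len(cells), params.mitosis_prob)
        for _ in range(n_mito_here):
            eligible = [
                c for c in _interior_cells(cells)
                if c in prev_ids and c not in shrinking
                and not any(e["frame"] == t + 1 and c in (e["parent"], *e["children"])
                            for e in events)
            ]
            rng.shuffle(eligible)
            for cid in eligible:  # first cell whose short-axis split succeeds
                res = _split_cell(cells, vertex_pos, int(cid), next_vid, next_cid)
                if res is None:
                    continue
                c1, c2, next_vid, next_cid = res
                sol.append(Hypothesis("mitosis", int(cid), (c1, c2), 0.0))
                events.append({"frame": t + 1, "kind": "mitosis", "parent": int(cid),
                               "children": (c1, c2)})
                break

        # start apoptoses scheduled to *collapse* two transitions later
        n_apo_here = apo_frames.count(t + 1)
        if params.n_apoptosis == 0 and params.apoptosis_prob > 0:
            n_apo_here = rng.binomial(len(cells), params.apoptosis_prob)
        for _ in range(n_apo_here):
            touched = {e["parent"] for e in events} | {c for e in events for c in e["children"]}
            eligible = [
                c for c in _interior_cells(cells)
                if c not in shrinking and c not in touched
            ]
            if eligible:
                shrinking[int(rng.choice(eligible))] = 2

        # associations for everything still present on both sides
        for cid in sorted(prev_ids & set(cells)):
            sol.append(Hypothesis("association", cid, (cid,), 0.0))
        true_solutions.append(sol)
        frames.append(snapshot(t + 1))

    return TissueSequence(params=params, frames=frames, true_solutions=true_solutions,
                          events=events)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_volume(
    frame: TissueFrame, params: RenderParams | None = None, time_index: int | None = None
) -> ImageVolume:
    """Render one ground-truth frame as a confocal-like image volume.

    The junctional belt is drawn as bright walls along AJ edges hanging from
    the apical surface, with per-edge intensity unevenness and optional
    gaps; vesicles are bright puncta below the belt; bristle cells have all
    their junctions saturated.  The clean signal is blurred with the
    anisotropic Gaussian PSF and corrupted with Poisson noise at the photon
    scale (photon scale 0 yields an all-zero volume).
    """
    params = params or RenderParams()
    rng = np.random.default_rng(params.seed)
    sp = np.asarray(params.spacing)
    l = frame.domain_size
    depth = params.apical_z + frame.height_amplitude + params.belt_height + 2 * params.margin
    shape = (
        max(int(np.ceil(depth / sp[0])), 3),
        max(int(np.ceil((l + 2 * params.margin) / sp[1])), 3),
        max(int(np.ceil((l + 2 * params.margin) / sp[2])), 3),
    )
    signal = np.zeros(shape)
    offset = np.array([params.margin, params.margin, params.margin])  # (z, y, x) um

    bristle_cells = {
        cid for cid in frame.cells if rng.uniform() < params.bristle_probability
    }
    edge_owner: dict[tuple[int, int], list[int]] = _edge_cell_map(frame.cells)

    step = float(min(sp)) * 0.5
    for (u, v), owners in sorted(edge_owner.items()):
        p_u, p_v = frame.position3d(u), frame.position3d(v)
        seg_len = float(np.linalg.norm(p_v - p_u))
        if seg_len == 0:
            continue
        factor = params.junction_intensity * float(
            np.exp(params.unevenness * rng.normal())
        )
        if any(c in bristle_cells for c in owners):
            factor *= params.bristle_multiplier
        gap: tuple[float, float] | None = None
        if rng.uniform() < params.gap_probability:
            g0 = rng.uniform(0, 1 - params.gap_fraction)
            gap = (g0, g0 + params.gap_fraction)
        n_s = max(int(seg_len / step), 2)
        n_d = max(int(params.belt_height / step), 1)
        for i_s in range(n_s + 1):
            s = i_s / n_s
            if gap and gap[0] <= s <= gap[1]:
                continue
            base = p_u + s * (p_v - p_u)
            for i_d in range(n_d + 1):
                p = base + np.array([params.belt_height * i_d / n_d, 0.0, 0.0])
                vox = np.rint((p + offset) / sp).astype(int)
                if np.all(vox >= 0) and np.all(vox < shape):
                    signal[tuple(vox)] = max(signal[tuple(vox)], factor)

    # vesicle clutter below the belt
    sub_depth = depth - (params.apical_z + params.belt_height)
    n_ves = rng.poisson(params.vesicle_density * l * l * max(sub_depth, 0.0))
    for _ in range(n_ves):
        p = np.array([
            rng.uniform(params.apical_z + params.belt_height, depth),
            rng.uniform(0, l) + params.margin,
            rng.uniform(0, l) + params.margin,
        ])
        vox = np.rint(p / sp).astype(int)
        if np.all(vox >= 0) and np.all(vox < shape):
            signal[tuple(vox)] = max(
                signal[tuple(vox)], params.junction_intensity * params.vesicle_brightness
            )

    blurred = ndimage.gaussian_filter(signal, sigma=np.asarray(params.psf_widths) / sp)
    if params.photon_scale > 0:
        data = rng.poisson(blurred * params.photon_scale) / params.photon_scale
    else:
        data = np.zeros_like(blurred)
    return ImageVolume(
        data=data,
        spacing=tuple(sp),
        time_index=frame.index if time_index is None else time_index,
    )


def true_vertex_positions(frame: TissueFrame, params: RenderParams) -> np.ndarray:
    """Ground-truth AJ-vertex positions in the rendered volume, um (z, y, x).

    Vertices are the belt's mid-depth points of the junction corners, i.e.
    where the renderer draws the meeting line of the walls.
    """
    graph, _ = frame.aj_graph()
    off = np.array([params.margin] * 3)
    pos = graph.positions + off
    pos[:, 0] += params.belt_height / 2.0
    return pos


def corrupt_tracks(sequence: TissueSequence, factor: int = 2) -> TissueSequence:
    """Decimate a sequence, keeping every ``factor``-th frame.

    Events between surviving frames are re-attributed by composing the
    ground-truth lineage: a cell alive at both kept frames is an
    association; one whose two descendants are alive is a mitosis; one with
    no surviving descendant is a termination; cells without an ancestor are
    creations.  Mimics halving the acquisition rate, which doubles apparent
    per-frame displacements.
    """
    if factor < 2:
        raise ValueError("decimation factor must be >= 2")
    kept = list(range(0, len(sequence.frames), factor))
    new_frames = [sequence.frames[i] for i in kept]

    # lineage maps per original transition
    parent_of: list[dict[int, tuple[int, str]]] = []
    for sol in sequence.true_solutions:
        m: dict[int, tuple[int, str]] = {}
        for h in sol:
            if h.kind == "association":
                m[h.targets[0]] = (h.source, "association")
            elif h.kind == "mitosis":
                for tgt in h.targets:
                    m[tgt] = (h.source, "mitosis")
        parent_of.append(m)

    def ancestor_at(cid: int, t_hi: int, t_lo: int) -> int | None:
        """Trace a cell at frame t_hi back to its ancestor at frame t_lo."""
        cur = cid
        for t in range(t_hi - 1, t_lo - 1, -1):
            link = parent_of[t].get(cur)
            if link is None:
                return None
            cur = link[0]
        return cur

    new_solutions: list[list[Hypothesis]] = []
    new_events: list[dict] = []
    for pair_idx in range(len(kept) - 1):
        t0, t1 = kept[pair_idx], kept[pair_idx + 1]
        cells0 = set(sequence.frames[t0].cells)
        cells1 = set(sequence.frames[t1].cells)
        descendants: dict[int, list[int]] = {c: [] for c in cells0}
        for c1 in sorted(cells1):
            anc = ancestor_at(c1, t1, t0)
            if anc is not None and anc in descendants:
                descendants[anc].append(c1)
        sol: list[Hypothesis] = []
        for c0 in sorted(cells0):
            desc = descendants[c0]
            if len(desc) == 1:
                sol.append(Hypothesis("association", c0, (desc[0],), 0.0))
            elif len(desc) == 2:
                sol.append(Hypothesis("mitosis", c0, tuple(desc), 0.0))
                new_events.append({"frame": pair_idx + 1, "kind": "mitosis", "parent": c0,
                                   "children": tuple(desc)})
            elif len(desc) == 0:
                sol.append(Hypothesis("apoptosis", c0, (), 0.0))
                new_events.append({"frame": pair_idx + 1, "kind": "apoptosis",
                                   "parent": c0, "children": ()})
            else:  # > 2 descendants cannot be expressed as one event
                sol.append(Hypothesis("mitosis", c0, tuple(desc[:2]), 0.0))
        explained = {t for h in sol for t in h.targets}
        for c1 in sorted(cells1 - explained):
            sol.append(Hypothesis("enter", None, (c1,), 0.0))
        new_solutions.append(sol)

    reindexed = [
        TissueFrame(index=i, vertex_pos=f.vertex_pos, cells=f.cells,
                    domain_size=f.domain_size, height_amplitude=f.height_amplitude,
                    geometry=f.geometry)
        for i, f in enumerate(new_frames)
    ]
    return TissueSequence(params=sequence.params, frames=reindexed,
                          true_solutions=new_solutions, events=new_events)
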