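"""Adherens-junction and cell graphs.

The junctional network of an epithelium is modelled as an undirected spatial
graph ``G_A = (V_A, E_A)`` whose vertices are the points where three or more
cells meet and whose edges join contiguous vertices.  Because the apical
surface is a (possibly curved) monolayer, ``G_A`` is planar: its faces are the
cells.  The dual graph ``G_C`` (outer face removed) encodes cell adjacency.

Face enumeration on a graph embedded in 3D uses a rotation system: incident
edges at each vertex are ordered by angle in that vertex's local tangent
plane (estimated by PCA of neighbour offsets, with orientation made globally
consistent by breadth-first propagation).  This works for curved monolayers
without requiring a global 2D projection.

All positions are physical micrometres in ``(z, y, x)`` axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AJGraph",
    "Cell",
    "CellGraph",
    "enumerate_faces",
    "build_cell_graph",
    "polygon_moments",
    "union_boundary",
]


@dataclass
class AJGraph:
    """Undirected spatial graph of adherens-junction vertices.

    ``positions`` is ``(n, 3)`` in micrometres, ``(z, y, x)`` order; vertices
    are identified by their row index.  ``edges`` holds unordered index pairs.
    """

    positions: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        n = self.n_vertices
        seen: set[tuple[int, int]] = set()
        canon: list[tuple[int, int]] = []
        for u, v in self.edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) references missing vertex")
            e = (min(u, v), max(u, v))
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
            canon.append(e)
        self.edges = canon

    @property
    def n_vertices(self) -> int:
        return 0 if self.positions.size == 0 else self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_vertices)}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj


@dataclass
class Cell:
    """A cell: one inner face of the AJ graph plus its polygon moments.

    ``boundary`` is the clockwise-ordered ring of AJ-vertex indices (clockwise
    with respect to the outward apical normal).  Moments are physical:
    perimeter and width/length in um, area in um^2, centroid in um (z, y, x),
    rotation in radians in (-pi/2, pi/2] (elongation axes are unsigned).
    """

    id: int
    boundary: list[int]
    perimeter: float
    area: float
    centroid: np.ndarray
    width: float
    length: float
    rotation: float


@dataclass
class CellGraph:
    """Dual of the AJ graph with the outer face removed.

    Vertices are cells; an edge joins two cells iff their faces share at
    least one AJ edge.
    """

    cells: list[Cell]
    edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: int) -> Cell:
        for c in self.cells:
            if c.id == cell_id:
                return c
        raise KeyError(cell_id)

    def neighbors(self, cell_id: int) -> set[int]:
        out: set[int] = set()
        for a, b in self.edges:
            if a == cell_id:
                out.add(b)
            elif b == cell_id:
                out.add(a)
        return out

    def are_adjacent(self, a: int, b: int) -> bool:
        e = (min(a, b), max(a, b))
        return e in {(min(u, v), max(u, v)) for u, v in self.edges}


# ---------------------------------------------------------------------------
# rotation system & face enumeration
# ---------------------------------------------------------------------------


def _vertex_normals(graph: AJGraph) -> np.ndarray:
    """Per-vertex unit normals from PCA of neighbour offsets.

    The tangent plane at a vertex is spanned by the directions towards its
    neighbours; the normal is the smallest-variance principal axis.  Signs are
    made consistent by BFS propagation, rooted with a positive z component
    (the apical side in (z, y, x) order).
    """
    pos = graph.positions
    adj = graph.adjacency()
    n = graph.n_vertices
    normals = np.zeros((n, 3))
    for v in range(n):
        nb = adj[v]
        if not nb:
            normals[v] = (1.0, 0.0, 0.0)
            continue
        d = pos[nb] - pos[v]
        norms = np.linalg.norm(d, axis=1)
        norms[norms == 0] = 1.0
        d = d / norms[:, None]
        if len(nb) == 1:
            # any vector orthogonal to the single edge
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(ref, d[0])) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            nrm = np.cross(d[0], ref)
        else:
            cov = d.T @ d
            w, vecs = np.linalg.eigh(cov)
            nrm = vecs[:, 0]
            if w[0] > 0.99 * max(w[1], 1e-300):  # pragma: no cover - degenerate
                nrm = np.array([1.0, 0.0, 0.0])
        nn = np.linalg.norm(nrm)
        normals[v] = nrm / nn if nn > 0 else (1.0, 0.0, 0.0)

    # BFS sign propagation for a globally consistent orientation
    visited = np.zeros(n, dtype=bool)
    for root in range(n):
        if visited[root]:
            continue
        if normals[root][0] < 0:
            normals[root] = -normals[root]
        visited[root] = True
        stack = [root]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if not visited[u]:
                    if np.dot(normals[u], normals[v]) < 0:
                        normals[u] = -normals[u]
                    visited[u] = True
                    stack.append(u)
    return normals


def _rotation_system(graph: AJGraph) -> dict[int, list[int]]:
    """Cyclic (counter-clockwise in the tangent plane) neighbour order."""
    pos = graph.positions
    adj = graph.adjacency()
    normals = _vertex_normals(graph)
    rotation: dict[int, list[int]] = {}
    for v in range(graph.n_vertices):
        nb = adj[v]
        if len(nb) <= 2:
            rotation[v] = sorted(nb)
            continue
        nrm = normals[v]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, nrm)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, nrm) * nrm
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        angles = []
        for u in nb:
            d = pos[u] - pos[v]
            angles.append(np.arctan2(np.dot(d, e2), np.dot(d, e1)))
        order = np.argsort(angles, kind="stable")
        rotation[v] = [nb[i] for i in order]
    return rotation


def _connected(graph: AJGraph) -> bool:
    n = graph.n_vertices
    if n == 0:
        return True
    adj = graph.adjacency()
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


def _ring_perimeter(ring: list[int], pos: np.ndarray) -> float:
    p = 0.0
    for i, v in enumerate(ring):
        p += float(np.linalg.norm(pos[ring[(i + 1) % len(ring)]] - pos[v]))
    return p


def enumerate_faces(graph: AJGraph, drop_outer: bool = True) -> list[list[int]]:
    """Trace the faces of the embedded AJ graph.

    Every directed edge is used exactly once; the next edge out of a vertex is
    the successor of the reversed incoming edge in the vertex's rotation
    order.  The Euler identity ``|V| - |E| + |F| = 2`` is enforced before the
    outer face (the one of maximum perimeter) is removed.

    Returns each face as a closed walk of vertex indices (first vertex not
    repeated at the end).
    """
    if graph.n_edges == 0:
        return []
    if not _connected(graph):
        raise ValueError("face enumeration requires a connected graph")
    rotation = _rotation_system(graph)
    index_in_rotation = {
        (v, u): i for v, nbrs in rotation.items() for i, u in enumerate(nbrs)
    }
    unused: set[tuple[int, int]] = set()
    for u, v in graph.edges:
        unused.add((u, v))
        unused.add((v, u))
    faces: list[list[int]] = []
    while unused:
        u0, v0 = min(unused)
        walk = [u0]
        u, v = u0, v0
        while True:
            unused.discard((u, v))
            # successor of (v, u) in v's rotation order
            nbrs = rotation[v]
            i = index_in_rotation[(v, u)]
            w = nbrs[(i + 1) % len(nbrs)]
            u, v = v, w
            if (u, v) == (u0, v0):
                break
            walk.append(u)
        faces.append(walk)

    n_f = len(faces)
    euler = graph.n_vertices - graph.n_edges + n_f
    if euler != 2:
        # pinch points: vertices visited more than once within a face walk
        suspects: set[int] = set()
        for f in faces:
            seen: set[int] = set()
            for v in f:
                if v in seen:
                    suspects.add(v)
                seen.add(v)
        raise ValueError(
            f"non-planar embedding: |V|-|E|+|F| = {euler} != 2 "
            f"(suspect vertices: {sorted(suspects)[:10]})"
        )
    if not drop_outer:
        return faces
    perims = [_ring_perimeter(f, graph.positions) for f in faces]
    outer = int(np.argmax(perims))
    return [f for i, f in enumerate(faces) if i != outer]


# ---------------------------------------------------------------------------
# polygon moments
# ---------------------------------------------------------------------------


def _plane_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-fit plane of a 3D point ring: (origin, e1, e2, normal).

    The in-plane x axis ``e1`` is the projection of the global x axis (last
    array axis) so that rotation angles are comparable across cells; the
    normal is oriented towards +z (outward apical side).
    """
    origin = points.mean(axis=0)
    centered = points - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    normal = vt[2]
    if normal[0] < 0:
        normal = -normal
    ref = np.array([0.0, 0.0, 1.0])  # global x axis in (z, y, x) order
    e1 = ref - np.dot(ref, normal) * normal
    if np.linalg.norm(e1) < 1e-9:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, normal) * normal
    e1 /= np.linalg.norm(e1)
    # components are (z, y, x): an odd permutation of xyz, so the geometric
    # right-handed cross product is np.cross with arguments swapped
    e2 = np.cross(e1, normal)
    return origin, e1, e2, normal


def polygon_moments(boundary_positions: np.ndarray) -> dict[str, float | np.ndarray]:
    """Moments of a (possibly non-planar) closed polygon in 3D.

    Perimeter is the sum of 3D segment lengths.  Area, centroid and the shape
    covariance are computed on the projection onto the least-squares plane;
    the centroid is lifted back to 3D.  Width/length are ``4 sqrt(lambda)`` of
    the minor/major eigenvalues of the area-weighted covariance (so a
    rectangle of aspect 2 yields length/width = 2 exactly); rotation is the
    major-axis angle in the plane, in ``(-pi/2, pi/2]``.
    """
    pts = np.asarray(boundary_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("boundary must be (K>=3, 3)")
    k = pts.shape[0]
    perimeter = float(sum(np.linalg.norm(pts[(i + 1) % k] - pts[i]) for i in range(k)))

    origin, e1, e2, normal = _plane_basis(pts)
    centered = pts - origin
    xy = np.stack([centered @ e1, centered @ e2], axis=1)
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    signed_area = 0.5 * float(cross.sum())
    area = abs(signed_area)
    if area < 1e-12 * max(perimeter, 1.0) ** 2:
        raise ValueError("degenerate (collinear) polygon")
    cx = float(((x + x1) * cross).sum()) / (6.0 * signed_area)
    cy = float(((y + y1) * cross).sum()) / (6.0 * signed_area)
    # area-weighted second moments about the centroid
    sxx = float(((x * x + x * x1 + x1 * x1) * cross).sum()) / (12.0 * signed_area) - cx**2
    syy = float(((y * y + y * y1 + y1 * y1) * cross).sum()) / (12.0 * signed_area) - cy**2
    sxy = (
        float(((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum())
        / (24.0 * signed_area)
        - cx * cy
    )
    cov = np.array([[sxx, sxy], [sxy, syy]])
    w, vecs = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    width = 4.0 * float(np.sqrt(w[0]))
    length = 4.0 * float(np.sqrt(w[1]))
    major = vecs[:, 1]
    rotation = float(np.arctan2(major[1], major[0]))
    if rotation <= -np.pi / 2:
        rotation += np.pi
    elif rotation > np.pi / 2:
        rotation -= np.pi
    centroid = origin + cx * e1 + cy * e2
    return {
        "perimeter": perimeter,
        "area": area,
        "centroid": centroid,
        "width": width,
        "length": length,
        "rotation": rotation,
    }


def _ring_edges(ring: list[int]) -> set[tuple[int, int]]:
    out = set()
    for i, v in enumerate(ring):
        u = ring[(i + 1) % len(ring)]
        out.add((min(u, v), max(u, v)))
    return out


def _clockwise(ring: list[int], pos: np.ndarray) -> list[int]:
    """Orient a face ring clockwise w.r.t. the outward (+z-ish) face normal."""
    pts = pos[ring]
    origin, e1, e2, _ = _plane_basis(pts)
    xy = np.stack([(pts - origin) @ e1, (pts - origin) @ e2], axis=1)
    x, y = xy[:, 0], xy[:, 1]
    signed = 0.5 * float((x * np.roll(y, -1) - np.roll(x, -1) * y).sum())
    return ring[::-1] if signed > 0 else ring


def build_cell_graph(faces: list[list[int]], graph: AJGraph) -> CellGraph:
    """One Cell per inner face; dual edges join faces sharing an AJ edge."""
    pos = graph.positions
    cells: list[Cell] = []
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for cid, ring in enumerate(faces):
        ring = _clockwise(list(ring), pos)
        m = polygon_moments(pos[ring])
        cells.append(
            Cell(
                id=cid,
                boundary=ring,
                perimeter=m["perimeter"],  # type: ignore[arg-type]
                area=m["area"],  # type: ignore[arg-type]
                centroid=m["centroid"],  # type: ignore[arg-type]
                width=m["width"],  # type: ignore[arg-type]
                length=m["length"],  # type: ignore[arg-type]
                rotation=m["rotation"],  # type: ignore[arg-type]
            )
        )
        for e in _ring_edges(ring):
            edge_to_faces.setdefault(e, []).append(cid)
    dual_edges: set[tuple[int, int]] = set()
    for fids in edge_to_faces.values():
        if len(fids) == 2:
            a, b = fids
            if a != b:
                dual_edges.add((min(a, b), max(a, b)))
    return CellGraph(cells=cells, edges=sorted(dual_edges))


def union_boundary(ring1: list[int], ring2: list[int]) -> list[int] | None:
    """Merge two face rings that share a contiguous run of AJ edges.

    Shared edges are deleted and the combined boundary re-traced.  Returns
    ``None`` when the union is not a simple cycle (e.g. the rings share no
    edge, or the merge would pinch the boundary).
    """
    e1, e2 = _ring_edges(ring1), _ring_edges(ring2)
    shared = e1 & e2
    if not shared:
        return None
    keep = (e1 | e2) - shared
    if not keep:
        return None
    adj: dict[int, list[int]] = {}
    for u, v in keep:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    if any(len(nb) != 2 for nb in adj.values()):
        return None
    start = min(adj)
    walk = [start]
    prev, cur = None, start
    while True:
        a, b = adj[cur]
        nxt = b if a == prev else a
        if nxt == start:
            break
        walk.append(nxt)
        prev, cur = cur, nxt
        if len(walk) > len(keep):
            return None
    if len(walk) != len(keep):
        return None
    return walk
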