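"""Voronoi-constrained fast marching and AJ-graph construction.

Edges between detected junction vertices are found by growing a *supervertex*
region around each vertex: the wavefront travels at speed ``F(x)`` (high on
junctional signal, low elsewhere), so regions spread along junctions and
stall in the cell interiors.  Travel times solve the Eikonal equation

    F(x) |grad T_v(x)| = 1,      T_v(v) = 0,

by first-order upwind (Godunov) fast marching in physical units.  Each wave
is confined to its seed's Voronoi region; the supervertex of ``v`` is the set
of voxels of its Voronoi region reached within a travel-time budget ``T_E``.
Two vertices receive an AJ edge iff their supervertices touch (6-connected).
"""

from __future__ import annotations

import heapq

import numpy as np

from .graphs import AJGraph

__all__ = ["voronoi_labels", "fast_march_supervertices", "build_aj_graph"]


def voronoi_labels(
    vertices: np.ndarray,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Label every voxel with its nearest vertex in physical distance.

    ``vertices`` are micrometre positions, ``(n, 3)`` in (z, y, x) order.
    Ties go to the lowest vertex index.  Labels are 0-based vertex indices.
    """
    verts = np.atleast_2d(np.asarray(vertices, dtype=float))
    if verts.size == 0:
        raise ValueError("need at least one vertex")
    sp = np.asarray(spacing, dtype=float)
    grids = np.meshgrid(
        *[np.arange(s) * sp[i] for i, s in enumerate(shape)], indexing="ij"
    )
    coords = np.stack([g.ravel() for g in grids], axis=1)  # (nvox, 3) um
    labels = np.empty(coords.shape[0], dtype=np.int32)
    chunk = 1 << 16
    for start in range(0, coords.shape[0], chunk):
        block = coords[start : start + chunk]
        d2 = ((block[:, None, :] - verts[None, :, :]) ** 2).sum(axis=2)
        labels[start : start + chunk] = np.argmin(d2, axis=1)
    return labels.reshape(shape)


def _seed_voxels(
    vertices: np.ndarray,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    sp = np.asarray(spacing, dtype=float)
    vox = np.rint(np.atleast_2d(vertices) / sp).astype(int)
    for ax in range(3):
        vox[:, ax] = np.clip(vox[:, ax], 0, shape[ax] - 1)
    return vox


def _update_time(a: list[tuple[float, float]], inv_speed: float) -> float:
    """Godunov upwind solution of sum_i max(t - a_i, 0)^2 / h_i^2 = inv_speed^2."""
    a.sort()
    t = a[0][0] + a[0][1] * inv_speed
    use = 1
    while use < len(a) and t > a[use][0]:
        use += 1
        # solve sum_{i<use} (t - a_i)^2 / h_i^2 = inv_speed^2
        p = sum(1.0 / h**2 for v, h in a[:use])
        q = sum(v / h**2 for v, h in a[:use])
        r = sum(v**2 / h**2 for v, h in a[:use]) - inv_speed**2
        disc = q * q - p * r
        if disc < 0:
            use -= 1
            break
        t_new = (q + np.sqrt(disc)) / p
        if t_new < a[use - 1][0]:
            use -= 1
            break
        t = t_new
    return float(t)


def fast_march_supervertices(
    vertices: np.ndarray,
    speed: np.ndarray,
    voronoi: np.ndarray,
    spacing: tuple[float, float, float],
    t_threshold: float,
    init_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow supervertices by Eikonal fast marching confined to Voronoi regions.

    Parameters
    ----------
    vertices:
        Seed positions, micrometres, (n, 3) in (z, y, x) order.
    speed:
        Travel-speed field ``F`` (must be > 0 at every seed voxel).  Voxels
        with non-positive speed are impassable.
    voronoi:
        Voronoi label field from :func:`voronoi_labels`; a wave with origin
        ``v`` only ever occupies voxels whose Voronoi label is ``v``.
    spacing:
        Physical voxel size (z, y, x), micrometres.
    t_threshold:
        Supervertex travel-time budget ``T_E``; marching stops once the front
        exceeds it (times beyond it are not needed and remain +inf).
    init_radius:
        Radius (um) of the exact-initialisation ball around each seed: within
        it (and within the seed's Voronoi region) times are set to the exact
        point-source solution for locally constant speed, which removes the
        source-singularity error of first-order upwind marching.  Default:
        5x the largest voxel size.  Keep it below half the vertex separation
        when growing supervertices, so neighbouring balls cannot touch
        through non-junctional space.

    Returns
    -------
    labels, times:
        ``labels[x] = v`` iff ``voronoi[x] = v`` and ``T_v(x) <= T_E``
        (background is -1); ``times`` is the travel-time field (um per unit
        speed), +inf where unreached.
    """
    verts = np.atleast_2d(np.asarray(vertices, dtype=float))
    shape = speed.shape
    sp = tuple(float(s) for s in spacing)
    seeds = _seed_voxels(verts, shape, sp)
    times = np.full(shape, np.inf, dtype=np.float64)
    accepted = np.zeros(shape, dtype=bool)
    labels = np.full(shape, -1, dtype=np.int32)

    if init_radius is None:
        init_radius = 5.0 * max(sp)
    heap: list[tuple[float, int, int, int]] = []
    axes = [np.arange(s) * h for s, h in zip(shape, sp)]
    for i, (z, y, x) in enumerate(seeds):
        if speed[z, y, x] <= 0:
            raise ValueError(f"vertex {i} sits on a non-positive-speed voxel")
        times[z, y, x] = 0.0
        heapq.heappush(heap, (0.0, z, y, x))
        r_vox = [int(np.ceil(init_radius / h)) for h in sp]
        lo = [max(c - r, 0) for c, r in zip((z, y, x), r_vox)]
        hi = [min(c + r + 1, s) for c, r, s in zip((z, y, x), r_vox, shape)]
        sub = tuple(slice(a, b) for a, b in zip(lo, hi))
        zz, yy, xx = np.meshgrid(*[ax[s] for ax, s in zip(axes, sub)], indexing="ij")
        seed_pos = np.array([z, y, x]) * np.asarray(sp)
        dist = np.sqrt((zz - seed_pos[0]) ** 2 + (yy - seed_pos[1]) ** 2 + (xx - seed_pos[2]) ** 2)
        ball = (dist <= init_radius) & (voronoi[sub] == voronoi[z, y, x]) & (speed[sub] > 0)
        # straight-ray reciprocal-speed integral: exact to first order in
        # speed variation, removes the point-source singularity error
        sp_arr = np.asarray(sp)
        for off in np.argwhere(ball):
            idx = (lo[0] + off[0], lo[1] + off[1], lo[2] + off[2])
            target = np.array(idx) * sp_arr
            d = float(np.linalg.norm(target - seed_pos))
            if d == 0:
                continue
            n_samp = max(int(np.ceil(d / min(sp))) * 2, 2)
            ts = np.linspace(0.0, 1.0, n_samp + 1)
            pts = seed_pos[None, :] + ts[:, None] * (target - seed_pos)[None, :]
            vox_pts = np.rint(pts / sp_arr).astype(int)
            for ax in range(3):
                vox_pts[:, ax] = np.clip(vox_pts[:, ax], 0, shape[ax] - 1)
            f_samples = speed[tuple(vox_pts.T)]
            if np.any(f_samples <= 0):
                continue
            t0 = float(np.trapezoid(1.0 / f_samples, dx=d / n_samp))
            if t0 < times[idx]:
                times[idx] = t0
                heapq.heappush(heap, (t0, *idx))

    nz, ny, nx = shape
    while heap:
        t, z, y, x = heapq.heappop(heap)
        if accepted[z, y, x] or t > times[z, y, x]:
            continue
        if t > t_threshold:
            break
        accepted[z, y, x] = True
        labels[z, y, x] = voronoi[z, y, x]
        lab = voronoi[z, y, x]
        for dz, dy, dx, h in (
            (-1, 0, 0, sp[0]),
            (1, 0, 0, sp[0]),
            (0, -1, 0, sp[1]),
            (0, 1, 0, sp[1]),
            (0, 0, -1, sp[2]),
            (0, 0, 1, sp[2]),
        ):
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                continue
            if accepted[zz, yy, xx] or voronoi[zz, yy, xx] != lab:
                continue
            f = speed[zz, yy, xx]
            if f <= 0:
                continue
            # upwind neighbours of (zz, yy, xx) restricted to the same wave
            a: list[tuple[float, float]] = []
            for ax, (lo, hi, hh) in enumerate(
                (((zz - 1, yy, xx), (zz + 1, yy, xx), sp[0]),
                 ((zz, yy - 1, xx), (zz, yy + 1, xx), sp[1]),
                 ((zz, yy, xx - 1), (zz, yy, xx + 1), sp[2]))
            ):
                best = np.inf
                for (pz, py, px) in (lo, hi):
                    if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                        if accepted[pz, py, px] and voronoi[pz, py, px] == lab:
                            best = min(best, times[pz, py, px])
                if np.isfinite(best):
                    a.append((best, hh))
            if not a:
                continue
            t_new = _update_time(a, 1.0 / f)
            if t_new < times[zz, yy, xx]:
                times[zz, yy, xx] = t_new
                heapq.heappush(heap, (t_new, zz, yy, xx))

    labels[times > t_threshold] = -1
    return labels, times


def build_aj_graph(supervertices: np.ndarray, vertices: np.ndarray) -> AJGraph:
    """AJ graph: an edge wherever two supervertices share a 6-connected face."""
    verts = np.atleast_2d(np.asarray(vertices, dtype=float))
    edges: set[tuple[int, int]] = set()
    lab = supervertices
    for ax in range(3):
        a = np.moveaxis(lab, ax, 0)[:-1].ravel()
        b = np.moveaxis(lab, ax, 0)[1:].ravel()
        mask = (a >= 0) & (b >= 0) & (a != b)
        if mask.any():
            pairs = np.stack([a[mask], b[mask]], axis=1)
            lo = pairs.min(axis=1)
            hi = pairs.max(axis=1)
            for u, v in np.unique(np.stack([lo, hi], axis=1), axis=0):
                edges.add((int(u), int(v)))
    return AJGraph(positions=verts, edges=sorted(edges))
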