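"""Volume preprocessing: deconvolution, local equalization, membrane diffusion.

Three operators prepare raw confocal stacks for junction filtering:

* :func:`richardson_lucy_elasticnet` — Richardson-Lucy deconvolution for the
  Poisson imaging model, with an optional elastic-net prior (most voxels of a
  junctional reporter volume are expected to be zero).  The penalty enters
  the multiplicative update through the denominator, which keeps iterates
  non-negative; with zero weights the scheme reduces to classic RL.
* :func:`clahe_3d` — contrast-limited adaptive histogram equalization in 3D,
  evening out the junctional signal across the field of view.
* :func:`membrane_enhancing_diffusion` — anisotropic diffusion steered by the
  Hessian: strong smoothing tangential to plate-like structures, almost none
  across them, giving junction walls a uniform intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .volume import ImageVolume

__all__ = [
    "PSFModel",
    "DeconvolutionParams",
    "richardson_lucy_elasticnet",
    "clahe_3d",
    "membrane_enhancing_diffusion",
]


@dataclass
class PSFModel:
    """Anisotropic Gaussian point-spread function.

    ``widths`` are per-axis standard deviations in micrometres, (z, y, x)
    order — axial blur is typically several times the lateral one.  A width
    of exactly 0 on every axis denotes a delta (identity) kernel.
    """

    widths: tuple[float, float, float] = (0.8, 0.15, 0.15)
    truncate: float = 4.0

    def kernel(self, spacing: tuple[float, float, float]) -> np.ndarray:
        """Discrete kernel on the voxel grid, normalised to sum 1."""
        sig_vox = np.asarray(self.widths, dtype=float) / np.asarray(spacing)
        if np.any(sig_vox < 0):
            raise ValueError("PSF widths must be >= 0")
        radii = np.maximum(np.ceil(self.truncate * sig_vox).astype(int), 0)
        axes = [np.arange(-r, r + 1, dtype=float) for r in radii]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        k = np.ones_like(zz)
        for g, s in zip((zz, yy, xx), sig_vox):
            if s > 0:
                k = k * np.exp(-(g**2) / (2 * s**2))
        return k / k.sum()


@dataclass
class DeconvolutionParams:
    iterations: int = 30
    l1_weight: float = 0.0
    l2_weight: float = 0.0
    tolerance: float = 0.0  # early stop when relative update falls below

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.l1_weight < 0 or self.l2_weight < 0:
            raise ValueError("elastic-net weights must be >= 0")
        if not np.isfinite([self.l1_weight, self.l2_weight]).all():
            raise ValueError("elastic-net weights must be finite")


def richardson_lucy_elasticnet(
    volume: ImageVolume, psf: PSFModel, params: DeconvolutionParams
) -> ImageVolume:
    """Richardson-Lucy deconvolution with an elastic-net prior.

    The multiplicative update

        u <- u * K^T(d / (K u)) / (1 + l1 + 2 l2 u)

    maximises the Poisson likelihood penalised by ``l1 |u| + l2 u^2``; with
    ``l1 = l2 = 0`` this is the classic RL iteration.  Stops after
    ``iterations`` updates or when the mean relative change falls below the
    tolerance.
    """
    kernel = psf.kernel(volume.spacing)
    if any(ks > vs for ks, vs in zip(kernel.shape, volume.shape)):
        raise ValueError(
            f"PSF kernel {kernel.shape} larger than volume {volume.shape}"
        )
    if params.iterations == 0 or kernel.size == 1:
        return volume.with_data(volume.data.copy())
    d = volume.data
    u = d.copy()
    eps = 1e-12
    k_flip = kernel[::-1, ::-1, ::-1]
    for _ in range(params.iterations):
        blurred = fftconvolve(u, kernel, mode="same")
        ratio = d / np.maximum(blurred, eps)
        correction = fftconvolve(ratio, k_flip, mode="same")
        denom = 1.0 + params.l1_weight + 2.0 * params.l2_weight * u
        u_new = np.clip(u * correction / denom, 0.0, None)
        change = np.abs(u_new - u).sum() / max(u.sum(), eps)
        u = u_new
        if params.tolerance > 0 and change < params.tolerance:
            break
    return volume.with_data(u)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


def _tile_mappings(
    data: np.ndarray, tile_shape: tuple[int, int, int], clip_limit: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Per-tile clipped-histogram equalization mappings.

    Returns (mappings[tz,ty,tx,n_bins], bin_centers, n_tiles).
    """
    shape = data.shape
    n_tiles = tuple(int(np.ceil(s / t)) for s, t in zip(shape, tile_shape))
    pad = [(0, n * t - s) for n, t, s in zip(n_tiles, tile_shape, shape)]
    padded = np.pad(data, pad, mode="edge")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    maps = np.empty(n_tiles + (n_bins,))
    for tz in range(n_tiles[0]):
        for ty in range(n_tiles[1]):
            for tx in range(n_tiles[2]):
                tile = padded[
                    tz * tile_shape[0] : (tz + 1) * tile_shape[0],
                    ty * tile_shape[1] : (ty + 1) * tile_shape[1],
                    tx * tile_shape[2] : (tx + 1) * tile_shape[2],
                ]
                hist, _ = np.histogram(tile, bins=edges)
                hist = hist.astype(float)
                limit = max(clip_limit * tile.size, 1.0)
                excess = np.clip(hist - limit, 0.0, None).sum()
                hist = np.minimum(hist, limit) + excess / n_bins
                cdf = np.cumsum(hist)
                cdf /= cdf[-1]
                maps[tz, ty, tx] = cdf
    return maps, centers, n_tiles


def clahe_3d(
    volume: ImageVolume,
    tile_shape: tuple[int, int, int] = (8, 64, 64),
    clip_limit: float = 0.01,
    n_bins: int = 256,
) -> ImageVolume:
    """Contrast-limited adaptive histogram equalization on a 3D volume.

    The volume is scaled to [0, 1], split into tiles, and each tile's clipped
    histogram defines an equalization mapping; every voxel's output value is
    the trilinear interpolation of the mappings of the 8 surrounding tile
    centres.  Output lies in [0, 1] and within-tile intensity rank order is
    preserved (each mapping is monotone).  ``clip_limit`` is the maximum
    histogram-bin fraction of the tile before redistribution (1 = no limit).
    """
    if clip_limit <= 0 or clip_limit > 1:
        raise ValueError("clip_limit must be in (0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vmax = volume.data.max()
    if vmax == 0:
        return volume.with_data(volume.data.copy())
    data = volume.data / vmax
    maps, centers, n_tiles = _tile_mappings(data, tuple(tile_shape), clip_limit, n_bins)

    # fractional tile-centre coordinates of every voxel
    out = np.zeros_like(data)
    weights_total = np.zeros_like(data)
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in data.shape], indexing="ij")
    tile_f = [
        np.clip((c - (t - 1) / 2.0) / t, 0.0, n - 1)
        for c, t, n in zip(coords, tile_shape, n_tiles)
    ]
    lo = [np.floor(f).astype(int) for f in tile_f]
    frac = [f - l for f, l in zip(tile_f, lo)]
    hi = [np.minimum(l + 1, n - 1) for l, n in zip(lo, n_tiles)]

    # bin interpolation of each voxel's value
    bin_pos = np.clip(
        np.interp(data, centers, np.arange(len(centers), dtype=float)), 0, len(centers) - 1
    )
    b_lo = np.floor(bin_pos).astype(int)
    b_hi = np.minimum(b_lo + 1, len(centers) - 1)
    b_frac = bin_pos - b_lo

    for cz in (0, 1):
        for cy in (0, 1):
            for cx in (0, 1):
                tz = hi[0] if cz else lo[0]
                ty = hi[1] if cy else lo[1]
                tx = hi[2] if cx else lo[2]
                w = (
                    (frac[0] if cz else 1 - frac[0])
                    * (frac[1] if cy else 1 - frac[1])
                    * (frac[2] if cx else 1 - frac[2])
                )
                mapped = (
                    maps[tz, ty, tx, b_lo] * (1 - b_frac) + maps[tz, ty, tx, b_hi] * b_frac
                )
                out += w * mapped
                weights_total += w
    out /= np.maximum(weights_total, 1e-12)
    return volume.with_data(np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# membrane-enhancing diffusion
# ---------------------------------------------------------------------------


def membrane_enhancing_diffusion(
    volume: ImageVolume,
    sigma: float = 0.5,
    iterations: int = 50,
    dt: float = 0.0625,
    epsilon: float = 0.05,
) -> ImageVolume:
    """Hessian-steered anisotropic diffusion that smooths along junction walls.

    The diffusion tensor at each voxel is ``D = I - (1 - epsilon) n n^T``
    where ``n`` is the Hessian eigenvector of the most negative eigenvalue at
    physical scale ``sigma`` (the sheet normal of a bright wall): diffusivity
    is 1 tangential to the wall and ``epsilon`` across it.  Explicit
    divergence-form time stepping on the voxel grid; the stability bound
    ``dt <= 1/6`` (3D, diffusivity <= 1) is enforced before iterating.
    Total intensity is conserved up to discretization (relative drift well
    below 1% over 50 iterations).
    """
    if dt > 1.0 / 6.0:
        raise ValueError(f"dt={dt} exceeds the explicit stability bound 1/6")
    if iterations == 0:
        return volume.with_data(volume.data.copy())
    sp = np.asarray(volume.spacing)
    sig_vox = sigma / sp
    data = volume.data
    h = np.empty(data.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d2 = ndimage.gaussian_filter(data, sigma=sig_vox, order=order, mode="nearest")
            d2 /= sp[i] * sp[j]
            h[..., i, j] = d2
            h[..., j, i] = d2
    _, vecs = np.linalg.eigh(h)
    n = vecs[..., 0]  # sheet normal (most negative curvature direction)
    d_tensor = np.eye(3) - (1.0 - epsilon) * n[..., :, None] * n[..., None, :]

    u = data.copy()
    for _ in range(iterations):
        grads = np.stack(np.gradient(u), axis=-1)
        flux = np.einsum("...ij,...j->...i", d_tensor, grads)
        # conservative divergence: face fluxes (mean of adjacent cells), zero
        # flux through the domain boundary, telescoping sum preserves mass
        div = np.zeros_like(u)
        for ax in range(3):
            f = flux[..., ax]
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            face = 0.5 * (f[tuple(lo)] + f[tuple(hi)])
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)
            face = np.pad(face, pad)  # zero-flux boundaries
            div += np.diff(face, axis=ax)
        u = np.clip(u + dt * div, 0.0, None)
    return volume.with_data(u)
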