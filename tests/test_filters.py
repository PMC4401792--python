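"""Hessian junction filters: plateness, vertexness, vertex detection."""

import numpy as np
import pytest

from ajtrack.filters import (
    ScaleSpaceParams,
    VertexDetectionParams,
    detect_vertices,
    hessian_eigenvalues,
    plateness,
    plateness_from_eigenvalues,
    vertexness,
    vertexness_from_eigenvalues,
)
from ajtrack.volume import ImageVolume


def gaussian_slab(shape=(33, 33, 33), width=1.5, axis=0, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*[np.arange(s) * h for s, h in zip(shape, spacing)], indexing="ij")
    c = [(s // 2) * h for s, h in zip(shape, spacing)]
    return ImageVolume(np.exp(-((grids[axis] - c[axis]) ** 2) / (2 * width**2)), spacing)


def gaussian_blob(shape=(33, 33, 33), width=1.5, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*[np.arange(s) * h for s, h in zip(shape, spacing)], indexing="ij")
    c = [(s // 2) * h for s, h in zip(shape, spacing)]
    r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return ImageVolume(np.exp(-r2 / (2 * width**2)), spacing)


class TestHessianEigenvalues:
    def test_quadratic_profile(self):
        """I = -x^2 + const has one eigenvalue -2 sigma^2 and two zeros."""
        sp = (1.0, 1.0, 1.0)
        x = np.arange(33) - 16.0
        data = 400.0 - np.tile(x**2, (33, 33, 1))
        vol = ImageVolume(data, sp)
        eigs = hessian_eigenvalues(vol, sigma=2.0)
        centre = eigs[16, 16, 16]
        # -2 sigma^2 up to the discrete second-derivative kernel response
        assert abs(centre[0] - (-2.0 * 4.0)) < 0.02 * 8.0
        assert abs(centre[1]) < 1e-6 * 8.0 and abs(centre[2]) < 1e-6 * 8.0

    def test_constant_volume_all_zero(self):
        vol = ImageVolume(np.full((8, 8, 8), 5.0), (1, 1, 1))
        assert np.abs(hessian_eigenvalues(vol, 1.0)).max() < 1e-5

    def test_isotropic_blob_equal_eigenvalues(self):
        vol = gaussian_blob(width=2.0)
        eigs = hessian_eigenvalues(vol, 1.0)[16, 16, 16]
        assert np.abs(eigs - eigs.mean()).max() < 0.01 * abs(eigs.mean())

    def test_subresolution_scale_rejected(self):
        vol = gaussian_blob(spacing=(2.0, 0.5, 0.5))
        with pytest.raises(ValueError, match="resolvable"):
            hessian_eigenvalues(vol, 0.5)

    def test_anisotropic_sampling_consistency(self):
        """Same physical slab, different voxel grids: same eigenvalues."""
        iso = gaussian_slab(shape=(32, 32, 32), width=2.0, spacing=(1, 1, 1))
        aniso = gaussian_slab(shape=(65, 33, 33), width=2.0, spacing=(0.5, 1, 1))
        e_iso = hessian_eigenvalues(iso, 2.0)[16, 16, 16]
        e_aniso = hessian_eigenvalues(aniso, 2.0)[32, 16, 16]
        assert np.abs(e_iso - e_aniso).max() < 0.02 * np.abs(e_iso).max()


class TestPlateness:
    def test_constant_volume_zero(self):
        vol = ImageVolume(np.full((8, 8, 8), 3.0), (1, 1, 1))
        assert plateness(vol, ScaleSpaceParams(1.0, 1.0, 1)).max() == 0.0

    def test_peak_on_slab_midplane_at_matched_scale(self):
        vol = gaussian_slab(width=1.5)
        responses = {}
        for s in (0.5, 1.5, 4.5):
            eigs = hessian_eigenvalues(vol, s)
            responses[s] = plateness_from_eigenvalues(eigs, gamma=0.2)[16, 16, 16]
        assert responses[1.5] > responses[0.5]
        assert responses[1.5] > responses[4.5]
        p = plateness_from_eigenvalues(hessian_eigenvalues(vol, 1.5), gamma=0.2)
        assert np.unravel_index(np.argmax(p), p.shape)[0] == 16  # mid-plane

    def test_blob_scores_below_slab(self):
        slab = gaussian_slab(width=1.5)
        blob = gaussian_blob(width=1.5)
        ps = plateness_from_eigenvalues(hessian_eigenvalues(slab, 1.5), gamma=0.2)
        pb = plateness_from_eigenvalues(hessian_eigenvalues(blob, 1.5), gamma=0.2)
        assert pb[16, 16, 16] < 0.5 * ps[16, 16, 16]

    def test_bounded_unit_interval(self, rng):
        vol = ImageVolume(rng.uniform(0, 10, (16, 16, 16)), (1, 1, 1))
        p = plateness(vol, ScaleSpaceParams(1.0, 2.0, 2))
        assert p.min() >= 0.0 and p.max() <= 1.0


def y_junction_volume(spacing=(1.0, 0.5, 0.5), size=24.0, height=3.0):
    """Three junction walls meeting along a vertical line at the centre."""
    shape = (int(8 / spacing[0]), int(size / spacing[1]), int(size / spacing[2]))
    data = np.zeros(shape)
    c = np.array([size / 2, size / 2])
    z0, z1 = 2.0, 2.0 + height
    for ang in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3):
        d = np.array([np.sin(ang), np.cos(ang)])  # (y, x)
        for s in np.arange(0, size / 2, min(spacing) / 2):
            p = c + s * d
            for z in np.arange(z0, z1, spacing[0] / 2):
                vox = np.array([z / spacing[0], p[0] / spacing[1], p[1] / spacing[2]])
                vox = np.rint(vox).astype(int)
                if np.all(vox >= 0) and np.all(vox < shape):
                    data[tuple(vox)] = 1.0
    from scipy.ndimage import gaussian_filter

    return ImageVolume(gaussian_filter(data, 1.0), spacing), c


class TestVertexness:
    def test_constant_volume_zero(self):
        vol = ImageVolume(np.full((8, 8, 8), 3.0), (1, 1, 1))
        assert vertexness(vol, ScaleSpaceParams(1.0, 1.0, 1)).max() == 0.0

    def test_peaks_at_y_junction_line(self):
        vol, centre = y_junction_volume()
        v = vertexness(vol, ScaleSpaceParams(0.8, 1.6, 3))
        # per-slice argmax within 2 voxels of the true junction (y, x)
        sp = np.array(vol.spacing)
        true_vox = centre / sp[1:]
        for z in range(3, 5):
            iy, ix = np.unravel_index(np.argmax(v[z]), v[z].shape)
            assert np.linalg.norm(np.array([iy, ix]) - true_vox) <= 2.0

    def test_wall_interior_scores_low(self):
        vol, centre = y_junction_volume()
        v = vertexness(vol, ScaleSpaceParams(0.8, 1.6, 3))
        peak = v.max()
        sp = np.array(vol.spacing)
        # a point on one arm, far from the junction
        arm = centre + 8.0 * np.array([1.0, 0.0])
        vox = (int(3.5 / sp[0]), int(arm[0] / sp[1]), int(arm[1] / sp[2]))
        assert v[vox] < 0.1 * peak


class TestInvariances:
    def test_rotation_equivariance_90deg(self):
        vol = gaussian_slab(width=1.5, axis=1)  # slab normal along y; odd grid
        p1 = plateness(vol, ScaleSpaceParams(1.5, 1.5, 1))
        rotated = ImageVolume(np.rot90(vol.data, axes=(1, 2)).copy(), vol.spacing)
        p2 = plateness(rotated, ScaleSpaceParams(1.5, 1.5, 1))
        assert np.abs(np.rot90(p1, axes=(1, 2)) - p2).max() < 1e-9

    def test_intensity_scaling_preserves_argmax(self, rng):
        vol, _ = y_junction_volume()
        params = ScaleSpaceParams(0.8, 1.6, 2)
        v1 = vertexness(vol, params)
        v2 = vertexness(vol.with_data(vol.data * 7.3), params)
        assert np.argmax(v1) == np.argmax(v2)

    def test_raising_threshold_shrinks_detection_set(self):
        vol, _ = y_junction_volume()
        v = vertexness(vol, ScaleSpaceParams(0.8, 1.6, 2))
        prev = None
        for thr in (0.01, 0.05, 0.1, 0.3):
            det = detect_vertices(v, vol.spacing, VertexDetectionParams(thr, 1.0))
            dset = {tuple(np.round(p, 6)) for p in det}
            if prev is not None:
                assert dset <= prev
            prev = dset


class TestDetectVertices:
    def test_single_bump_single_detection(self):
        vol = gaussian_blob(width=2.0)
        field = vol.data
        det = detect_vertices(field, (1, 1, 1), VertexDetectionParams(0.5, 2.0))
        assert det.shape == (1, 3)
        assert np.abs(det[0] - 16.0).max() <= 0.5

    def test_threshold_above_max_gives_empty(self):
        vol = gaussian_blob(width=2.0)
        det = detect_vertices(vol.data, (1, 1, 1), VertexDetectionParams(2.0, 1.0))
        assert det.shape == (0, 3)

    def test_close_pair_merged_to_higher_peak(self):
        shape = (9, 21, 21)
        z, y, x = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        f = np.exp(-((z - 4) ** 2 + (y - 10) ** 2 + (x - 8) ** 2) / 4.0)
        f += 0.6 * np.exp(-((z - 4) ** 2 + (y - 10) ** 2 + (x - 12) ** 2) / 4.0)
        det = detect_vertices(f, (1, 1, 1), VertexDetectionParams(0.1, 5.0))
        assert det.shape == (1, 3)
        assert abs(det[0, 2] - 8.0) < 1.0  # kept the higher peak
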