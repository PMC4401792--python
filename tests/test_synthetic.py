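"""Synthetic tissue generator and renderer."""

import numpy as np
import pytest

from ajtrack.graphs import enumerate_faces
from ajtrack.synthetic import (
    RenderParams,
    TissueSimulationParams,
    corrupt_tracks,
    generate_tissue_sequence,
    render_volume,
    true_vertex_positions,
)


class TestGenerateSequence:
    def test_same_seed_identical_output(self):
        s1 = generate_tissue_sequence(TissueSimulationParams(seed=3))
        s2 = generate_tissue_sequence(TissueSimulationParams(seed=3))
        for f1, f2 in zip(s1.frames, s2.frames):
            assert f1.cells == f2.cells
            for v in f1.vertex_pos:
                assert np.array_equal(f1.vertex_pos[v], f2.vertex_pos[v])
        assert s1.events == s2.events

    def test_no_events_no_drift_keeps_topology(self):
        params = TissueSimulationParams(
            n_cells=20, n_frames=5, n_mitosis=0, n_apoptosis=0,
            jacobian=np.zeros((2, 2)), drift=np.zeros(2), jitter=0.0, seed=1,
        )
        seq = generate_tissue_sequence(params)
        first = seq.frames[0]
        for f in seq.frames[1:]:
            assert f.cells == first.cells
            for v in first.vertex_pos:
                assert np.allclose(f.vertex_pos[v], first.vertex_pos[v])

    def test_cell_count_bookkeeping(self, standard_sequence):
        """N_{t+1} = N_t + mitoses - apoptoses on every transition."""
        seq = standard_sequence
        for t, sol in enumerate(seq.true_solutions):
            kinds = [h.kind for h in sol]
            n0 = len(seq.frames[t].cells)
            n1 = len(seq.frames[t + 1].cells)
            assert n1 == n0 + kinds.count("mitosis") - kinds.count("apoptosis")

    def test_scheduled_event_counts_realised(self, standard_sequence):
        kinds = [e["kind"] for e in standard_sequence.events]
        assert kinds.count("mitosis") == standard_sequence.params.n_mitosis
        assert kinds.count("apoptosis") == standard_sequence.params.n_apoptosis

    def test_every_frame_topologically_valid(self, standard_sequence):
        """Planarity (Euler) and face/ground-truth agreement each frame."""
        for frame in standard_sequence.frames:
            g, index = frame.aj_graph()
            faces = enumerate_faces(g)
            assert len(faces) == len(frame.cells)
            truth = {frozenset(index[v] for v in r) for r in frame.cells.values()}
            assert {frozenset(f) for f in faces} == truth

    def test_mitosis_children_adjacent(self, standard_sequence):
        seq = standard_sequence
        for e in seq.events:
            if e["kind"] != "mitosis":
                continue
            frame = seq.frames[e["frame"]]
            _, cg, _ = frame.cell_objects()
            c1, c2 = e["children"]
            assert cg.are_adjacent(c1, c2)

    def test_tube_geometry_positions_on_cylinder(self):
        params = TissueSimulationParams(n_cells=16, n_frames=2, n_mitosis=0,
                                        n_apoptosis=0, geometry="tube", seed=2)
        seq = generate_tissue_sequence(params)
        f = seq.frames[0]
        r = params.domain_size / (2 * np.pi)
        for vid in f.vertex_pos:
            z, y, x = f.position3d(vid)
            assert np.hypot(z - r, x - r) == pytest.approx(r, rel=1e-9)


class TestRenderVolume:
    def test_zero_photon_scale_gives_zero_volume(self, standard_sequence):
        vol = render_volume(standard_sequence.frames[0], RenderParams(photon_scale=0.0))
        assert vol.data.max() == 0.0

    def test_clean_signal_lies_on_junctions(self, standard_sequence):
        """Without noise or clutter, the brightest voxels sit on drawn walls."""
        frame = standard_sequence.frames[0]
        rp = RenderParams(photon_scale=1e9, vesicle_density=0.0, unevenness=0.0,
                          gap_probability=0.0, bristle_probability=0.0,
                          psf_widths=(1e-6, 1e-6, 1e-6))
        vol = render_volume(frame, rp)
        g, _ = frame.aj_graph()
        off = np.array([rp.margin] * 3)
        sp = np.array(vol.spacing)
        bright = np.argwhere(vol.data > 0.5 * vol.data.max())
        # each bright voxel within one voxel of some wall segment
        segs = [(g.positions[u] + off, g.positions[v] + off) for u, v in g.edges]
        for vox in bright[:: max(len(bright) // 50, 1)]:
            p = vox * sp
            best = np.inf
            for a, b in segs:
                for depth in (0.0, rp.belt_height / 2, rp.belt_height):
                    aa = a + [depth, 0, 0]
                    bb = b + [depth, 0, 0]
                    ab = bb - aa
                    t = np.clip((p - aa) @ ab / max(ab @ ab, 1e-12), 0, 1)
                    best = min(best, np.linalg.norm(p - (aa + t * ab)))
                    if best < 0.7:
                        break
                if best < 0.7:
                    break
            assert best < 0.7

    def test_poisson_noise_unbiased(self, standard_sequence):
        """Mean of repeated noisy renders approaches the noiseless signal.

        Structural randomness (unevenness, gaps, clutter) is switched off so
        that renders differ only in their Poisson draws.
        """
        frame = standard_sequence.frames[0]
        fixed = dict(unevenness=0.0, gap_probability=0.0, vesicle_density=0.0,
                     bristle_probability=0.0)
        clean = render_volume(frame, RenderParams(seed=0, photon_scale=1e9, **fixed)).data
        acc = np.zeros(clean.shape)
        n = 50
        for k in range(n):
            acc += render_volume(
                frame, RenderParams(seed=100 + k, photon_scale=50.0, **fixed)
            ).data
        mean = acc / n
        mask = clean > 0.2
        se = np.sqrt(clean[mask] / 50.0 / n)
        resid = np.abs(mean[mask] - clean[mask])
        assert (resid < 3 * se).mean() > 0.95

    def test_determinism(self, standard_sequence):
        f = standard_sequence.frames[0]
        v1 = render_volume(f, RenderParams(seed=5))
        v2 = render_volume(f, RenderParams(seed=5))
        assert np.array_equal(v1.data, v2.data)

    def test_true_vertex_positions_inside_volume(self, standard_sequence):
        rp = RenderParams()
        vol = render_volume(standard_sequence.frames[0], rp)
        pos = true_vertex_positions(standard_sequence.frames[0], rp)
        vox = pos / np.array(vol.spacing)
        assert np.all(vox >= 0) and np.all(vox < np.array(vol.shape))


class TestCorruptTracks:
    def test_keeps_every_kth_frame(self, standard_sequence):
        dec = corrupt_tracks(standard_sequence, 2)
        assert len(dec.frames) == 5
        for i, f in enumerate(dec.frames):
            assert f.cells == standard_sequence.frames[2 * i].cells

    def test_event_free_decimation_preserves_track_count(self):
        params = TissueSimulationParams(n_cells=20, n_frames=6, n_mitosis=0,
                                        n_apoptosis=0, seed=4)
        seq = generate_tissue_sequence(params)
        dec = corrupt_tracks(seq, 2)
        for sol in dec.true_solutions:
            assert all(h.kind == "association" for h in sol)
            assert len(sol) == 20

    def test_displacements_double_under_factor_two(self):
        params = TissueSimulationParams(n_cells=20, n_frames=6, n_mitosis=0,
                                        n_apoptosis=0, jitter=0.0, seed=4)
        seq = generate_tissue_sequence(params)
        dec = corrupt_tracks(seq, 2)

        def mean_step(s):
            d = []
            for t in range(len(s.frames) - 1):
                f0, f1 = s.frames[t], s.frames[t + 1]
                for v in set(f0.vertex_pos) & set(f1.vertex_pos):
                    d.append(np.linalg.norm(f1.vertex_pos[v] - f0.vertex_pos[v]))
            return np.mean(d)

        assert mean_step(dec) == pytest.approx(2 * mean_step(seq), rel=0.05)

    def test_events_reattributed(self, standard_sequence):
        dec = corrupt_tracks(standard_sequence, 2)
        kinds = [e["kind"] for e in dec.events]
        assert kinds.count("mitosis") == standard_sequence.params.n_mitosis
        assert kinds.count("apoptosis") == standard_sequence.params.n_apoptosis

    def test_factor_below_two_rejected(self, standard_sequence):
        with pytest.raises(ValueError):
            corrupt_tracks(standard_sequence, 1)
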