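# ajtrack

Segmentation and tracking of epithelial cells from 3D adherens-junction
imaging.

In live confocal imaging of epithelia labelled with a junctional reporter
(E-cadherin::GFP), each cell appears as a bright belt of adherens junctions
(AJs) hanging from the apical surface — not as a closed membrane. `ajtrack`
is for developmental biologists and image analysts who want cell outlines,
lineages and tissue kinematics from exactly this kind of data, without a
nuclei channel and without projecting to 2D:

* **Junction filters.** Plateness `P(x)` and vertexness `V(x)` are built
  from the eigenvalues `λ1 ≤ λ2 ≤ λ3` of the scale-normalised Gaussian
  Hessian, in physical units (anisotropic voxels handled throughout). `P`
  is high on wall-like sheets (`λ1 ≪ 0`, `|λ2|` small); `V` peaks where
  three or more walls meet and all curvatures turn negative. AJ vertices
  are thresholded local maxima of `V`.
* **Supervertex region growing.** Travel times from each vertex solve the
  Eikonal equation `F(x)·|∇T_v(x)| = 1` with speed `F = P + V` by
  Voronoi-constrained fast marching; the supervertex of `v` is
  `{x ∈ Voronoi(v) : T_v(x) ≤ T_E}`. An edge of the AJ graph
  `G_A = (V_A, E_A)` joins two vertices iff their supervertices touch.
* **Cells as faces.** `G_A` is planar; its inner faces are the cells, and
  the dual graph `G_C` (outer face removed) encodes cell adjacency. Each
  cell polygon yields perimeter, area, centroid, width, length and
  rotation.
* **Tracking.** Frame-to-frame correspondence is a coupled minimum-cost
  assignment over association, enter, leave, mitosis and apoptosis
  hypotheses (11 weights: 6 moment features + 5 hypothesis kinds), with
  mitosis siblings required to be adjacent and costed against the parent
  via their merged polygon. Solved exactly; lineage recorded.
* **Kinematics.** Centroid tracks are smoothed under a constant-velocity
  linear-Gaussian model (the MAP sequence, equal to the RTS smoother
  mean); per frame the cell velocity field is regressed as
  `ṗ = J·p + ṗ₀`, and `J = E + Ω` splits into expansion
  (`trace(E)`) and rotation.
* **Synthetic tissue.** A generator produces ground-truth cell packings
  with prescribed affine drift, mitoses and apoptoses, and renders them as
  confocal-like stacks (uneven belts with gaps, vesicle clutter, bristle
  cells, PSF blur, Poisson noise), so every stage is testable without data
  downloads. Evaluation utilities (precision/recall/F1 within a matching
  radius, PR sweeps, tracking AF1) close the loop.

## Worked example

```python
import numpy as np
from ajtrack import (TissueSimulationParams, RenderParams, generate_tissue_sequence,
                     render_volume, segment_volume)
from ajtrack.pipeline import FilterConfig, GraphConfig
from ajtrack.preprocess import clahe_3d
from ajtrack.synthetic import true_vertex_positions
from ajtrack.evaluation import match_vertices, MatchParams, precision_recall_f1

seq = generate_tissue_sequence(TissueSimulationParams(seed=0))
frame = seq.frames[0]
print(f"simulated tissue: {len(frame.cells)} cells, "
      f"{len(frame.vertex_pos)} junction vertices")

rp = RenderParams(seed=0)
vol = clahe_3d(render_volume(frame, rp), tile_shape=(12, 33, 33), clip_limit=0.02)
print(f"rendered volume: shape {vol.shape}, spacing {vol.spacing} um")

seg = segment_volume(vol, FilterConfig(), GraphConfig())
g = seg["aj_graph_pruned"]
print(f"segmented: {len(seg['vertices'])} vertices, {g.n_edges} edges, "
      f"{seg['cell_graph'].n_cells} cells")

truth = true_vertex_positions(frame, rp) / np.array(vol.spacing)
tp, fp, fn, _ = match_vertices(seg["vertices"] / np.array(vol.spacing), truth,
                               MatchParams(2.0))
p, r, f1 = precision_recall_f1(tp, fp, fn)
print(f"vertex detection vs ground truth: precision {p:.3f}, recall {r:.3f}, F1 {f1:.3f}")
```

prints

```
simulated tissue: 50 cells, 93 junction vertices
rendered volume: shape (12, 132, 132), spacing (0.6, 0.25, 0.25) um
segmented: 95 vertices, 174 edges, 80 cells
vertex detection vs ground truth: precision 0.874, recall 0.892, F1 0.883
```

A 50-cell patch is simulated, rendered at realistic noise, locally
equalized, and segmented end to end: 95 vertex detections against 93 true
junction vertices, with 87% of detections correct and 89% of true vertices
found within the 2-voxel matching radius. The 80 faces include the 50 true
cells plus small spurious faces from surplus detections; downstream
tracking and kinematics consume the cells table (see
`ajtrack.pipeline.run_pipeline` for the full chain through tracks and
strain-rate tensors, or the `ajtrack` command line:
`simulate`, `preprocess`, `segment`, `track`, `strain`, `evaluate`, `run`).

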