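# Methods

This note records the models, algorithms and numerical choices behind
`ajtrack`, and what the synthetic test bed does and does not establish about
behaviour on real microscopy data.

## Problem setting

Live imaging of epithelia with a junctional reporter (E-cadherin::GFP) shows
each cell as a bright belt: the adherens junctions (AJs) form short walls
hanging from the apical surface along every cell–cell interface. Unlike a
full membrane label, the AJ signal does not enclose cells in 3D, so
watershed-style volume segmentation does not apply. `ajtrack` instead
recovers the *junctional graph*: vertices where three or more cells meet,
edges along shared interfaces, and cells as the faces of that (planar)
graph. Cells are then tracked through time, and tissue-scale kinematics are
summarised by a strain-rate tensor.

Axis convention: all arrays are `(z, y, x)`; all positions are physical
micrometres in the same order. Confocal stacks are strongly anisotropic
(z step ~0.6–1.5 µm vs 0.1–0.3 µm laterally), so every filter works in
physical units via per-axis Gaussian widths.

## Preprocessing

* **Richardson–Lucy with elastic-net prior.** The Poisson imaging model's
  multiplicative update is augmented with the penalty `l1·|u| + l2·u²`
  through the denominator, `u ← u · Kᵀ(d/(Ku)) / (1 + l1 + 2·l2·u)`, which
  preserves non-negativity and reduces to classic RL at `l1 = l2 = 0`
  (verified against an independently coded textbook iteration to 1e-6).
  The PSF is an anisotropic Gaussian (defaults 0.8 µm axial, 0.15 µm
  lateral — a standard confocal approximation; the true PSF should be
  supplied when known). Deconvolution is off by default in the pipeline: the
  junction filters work on blurred data, and the synthetic renderer's blur
  is mild.
* **3D CLAHE.** Per-tile clipped-histogram equalization with trilinear
  interpolation between tile mappings. With a single tile and clip limit 1
  it equals global histogram equalization exactly; within-tile rank order is
  always preserved. Defaults: tiles 12×33×33 voxels, clip 0.02, 256 bins —
  tile extent a few cell diameters, so per-cell contrast is kept while
  field-scale unevenness (and very bright cells) are flattened. CLAHE is the
  one preprocessing step the default pipeline applies: the filters' contrast
  gate benefits directly from an even belt intensity.
* **Membrane-enhancing diffusion.** Explicit anisotropic diffusion with
  tensor `D = I − (1−ε)·n nᵀ`, `n` the Hessian eigenvector of the most
  negative eigenvalue (the wall normal) at scale `sigma`: diffusivity 1
  along the wall, `ε = 0.05` across it. Divergence is discretised in
  conservative (staggered face-flux) form with zero-flux boundaries, so
  total intensity is conserved to machine precision; `dt ≤ 1/6` is enforced
  (3D explicit stability bound at unit diffusivity on the voxel grid).
  50 iterations at `dt = 0.0625` roughly halve in-plane noise twice over
  without measurably widening the wall cross-section. Optional; not part of
  the default pipeline.

## Junction filters

All measures come from the eigenvalues `l1 ≤ l2 ≤ l3` of the
gamma-normalised (σ²-scaled) Gaussian Hessian, computed with per-axis widths
`σ/spacing` and divided by the voxel sizes (true physical derivatives). The
volume mean is subtracted before filtering so the discrete derivative
kernels are exactly zero-sum (a constant volume yields identically zero
eigenvalues); kernels are truncated at 8σ.

* **Plateness** (wall likelihood): `exp(−(l2/l1)²/2α²) · (1 − exp(−S²/2γ²))`
  where `l1 < 0`, `S = ‖(l1,l2,l3)‖` and `α = 0.5`. High for one strong
  negative curvature (across the wall) and little else.
* **Vertexness** (meeting-point likelihood): where ≥ 3 walls meet, intensity
  curves downward in *every* direction, so all three eigenvalues are
  negative — exactly where plateness dips. The measure is
  `sqrt(l2·l3/l1²)` gated to `l1,l2,l3 < 0`, times the same contrast term.
  Wall interiors (`l3 ≥ 0`) score zero; isotropic blobs (vesicles) score by
  their much weaker contrast.
* The contrast scale `γ` defaults to half the 99th percentile of `S`:
  normalising by the maximum proved fragile when a few very bright
  bristle-cell junctions dominate the volume. Voxels whose structureness or
  leading curvature is at numerical-noise level are gated out, which also
  makes the fields exactly equivariant under grid-preserving rotations.
* Responses are combined over `n_scales` log-spaced σ in
  `[sigma_min, sigma_max]` (defaults 0.4–0.8 µm, 3 scales) by voxelwise
  maximum: small scales split close vertices, large scales merge them, and
  the maximum keeps the best of each.
* **Vertex detection**: plateau-tolerant 26-neighbourhood local maxima of
  vertexness with response ≥ threshold (default 0.2, calibrated on the
  synthetic suite); candidates closer than `min_separation` (1.2 µm,
  just under a typical minimal junction length) are merged keeping the
  higher response, ties to the lower lexicographic voxel index. Positions
  are refined per axis by quadratic interpolation (voxel centre when
  non-concave) and reported in micrometres.

## Supervertices and the AJ graph

Each detected vertex seeds a wave that travels at speed `F = P + V`
(clipped below at 1e-6 to stay positive): fast along junctions, stalled in
cell interiors and background. Travel times solve the Eikonal equation
`F·|∇T| = 1` by first-order upwind (Godunov) fast marching in physical
units. Two deliberate restrictions:

* a wave never crosses its seed's Voronoi region (labels from an exact
  brute-force nearest-vertex scan, ties to the lowest index), so regions
  cannot swallow each other;
* within an *exact-initialisation ball* around each seed (default radius
  5 voxels; the pipeline passes `min_separation/2` so neighbouring balls
  cannot meet outside junctions) times are set by a straight-ray
  reciprocal-speed integral. This removes the point-source singularity
  error of first-order upwind schemes, which otherwise reaches ~20% along
  diagonals; with it, unit-speed times agree with Euclidean distance and
  random-speed times with a long-stencil Dijkstra reference to within 5%.

The supervertex of `v` is the part of its Voronoi region with `T ≤ T_E`
(default budget 16 — roughly half an edge of travel at the typical
junction speed of ~0.2–0.4 after CLAHE). An AJ edge joins `v, w` iff their
supervertices share a 6-connected voxel face (the strictest touch
criterion; diagonal contact through a one-voxel wall does not count).
Raising `T_E` only ever adds edges (tested property), which is what makes
precision–recall sweeps over `T_E` meaningful.

## Cells as faces

Faces of the embedded AJ graph are traced with a rotation system: at each
vertex, incident edges are ordered by angle in the local tangent plane (PCA
of neighbour offsets; normal signs made globally consistent by BFS
propagation, rooted towards the apical side). This works on curved
monolayers — height-field patches or tubes — without a global 2D
projection. Every directed edge is used exactly once; the Euler identity
`|V| − |E| + |F| = 2` is enforced before the outer face (maximum perimeter,
robust for elongated crops) is removed. On imperfect, end-to-end segmented
graphs the pipeline additionally prunes dangling vertices, keeps the
largest component, and — if tracing still fails — removes the reported
pinch vertices and retries.

Cell moments: perimeter from 3D segment lengths; area, centroid and shape
from the projection onto the least-squares plane (in-plane x axis aligned
with the global x axis so orientations are comparable across cells).
Width/length are `4·sqrt(eigenvalue)` of the area-weighted polygon
covariance — for a rectangle this reproduces the side ratio exactly — and
rotation is the major-axis angle in `(−π/2, π/2]` (elongation axes are
unsigned). The dual cell graph joins faces sharing at least one AJ edge.

## Tracking

Each frame pair is a coupled assignment: every cell at `t` and every cell
at `t+1` must be explained exactly once by one of five hypothesis kinds —
association, mitosis (two siblings, required to be adjacent in the `t+1`
cell graph; the parent is compared against the merged polygon of the two
children), apoptosis (cost ∝ area: dying cells have shrunk), enter and
leave (cost ∝ centroid distance to the tissue boundary: cells only
plausibly appear or vanish near the field edge). Association and mitosis
candidates are gated to 3× the median cell diameter, standing in for
sheet-neighbourhood adjacency while bounding the network.

The 11 parameters are 6 feature weights and 5 hypothesis weights. Feature
differences are normalised by their median absolute difference over the
frame pair's candidate pairs (floored at 5% of the feature's typical size),
making the weights dimensionless. Defaults were set by grid search on the
synthetic suite: centroid 16, area/perimeter 0.5, width/rotation/length
0.25, association offset 1, enter/leave 2 per µm, mitosis offset 8,
apoptosis 0.5 per µm². The centroid-dominant balance matters: a
pre-apoptotic cell changes shape violently between frames, and
shape-dominated costs mislabel its last associations as spurious
mitosis/apoptosis pairs; centroids barely move under shrinkage.

The minimum-cost selection is computed exactly as a small integer program
(HiGHS via `scipy.optimize.milp`), with costs rounded at 1e-6 resolution
and an infinitesimal lexicographic perturbation for deterministic
tie-breaking. An exhaustive-enumeration oracle confirms optimality on
random instances (≤ 6 cells/frame); conservation —
`associations + leaves + apoptoses + mitoses = N` and
`associations + enters + 2·mitoses = M` — is asserted on every solution.
Frame-pair solutions are stitched into tracks with recorded lineage.

## Kinematics

Centroid trajectories (z dropped; the tissues analysed are nearly planar)
follow a constant-velocity linear-Gaussian model with the transition and
observation matrices fixed by that model (unit time step of one frame). The
most probable state sequence — what Viterbi decoding returns for this
chain — equals the Rauch–Tung–Striebel smoother mean, which is how it is
computed; a dense joint-Gaussian posterior-mode oracle confirms agreement
to 1e-8. Defaults: observation noise (0.1 µm)² (sub-voxel; polygon
centroids average many vertices), velocity process noise 0.05 (µm/frame)²
so spatially varying flows are not over-smoothed into a bias. Velocities
are per frame; multiply by the frame interval for µm/min.

Per frame, the velocity field over cells is fitted by ordinary least
squares as `ṗ = J·p + ṗ₀`. `J` splits into symmetric `E` (areal expansion
rate = trace) and antisymmetric `Ω`. Two rotation readouts are emitted:
`acos(Ω₁₂)` (the literal convention, NaN outside [−1,1]) and
`asin(−Ω₁₂)`, the frame-to-frame rigid rotation angle, which is the
dimensionally standard rate. Tracks shorter than 3 frames are excluded
from the fit.

## Evaluation

Vertex detections are matched one-to-one to annotations by minimum-cost
assignment restricted to pairs within 2 voxels; edges are true positives
iff both endpoints match and the matched annotated vertices are connected
in the truth. Edge scoring supports both end-to-end mode and the
annotation-seeded mode (supervertices grown from the annotated vertex
positions), the latter isolating edge recovery from vertex-detection
errors. `tp = 0` yields precision = recall = F1 = 0 (logged). Tracking is
scored per cell as label prediction; AF1 is the harmonic mean of the
association, creation (enter + mitosis child), termination (leave +
apoptosis) and mitosis F1 scores; a category absent from both truth and
prediction scores 1 (logged).

## Synthetic tissue

The generator is the study's test bed. Frame 0 is a Lloyd-relaxed bounded
Voronoi packing (4 iterations; mirror-padded seeds) — a mildly disordered
polygonal packing like a real epithelium; junction edges shorter than
0.4 µm are contracted (random Voronoi diagrams contain arbitrarily short
edges that would flip under jitter), yielding occasional rosette vertices
as real tissues show. Defaults define the standard scenario: 50 cells on a
30 µm planar patch (cell diameter ~4.5 µm), 10 frames, affine drift with
`J = [[0.008, 0.004], [−0.004, 0.006]]` per frame about the patch centre
plus (0.25, 0.15) µm/frame translation (≈1%/frame expansion with a slight
rotation — the scale of pupal notum flows at 10-minute sampling), 0.05 µm
per-vertex jitter, 3 mitoses and 2 apoptoses at scheduled, evenly spread
transitions. A mitosis splits a face along its short axis (two new
vertices, one new junction — the children are adjacent by construction);
an apoptosis shrinks its cell towards the centroid for two transitions
(factor 0.45 each) and then collapses it to a single vertex, neighbours
closing over. The apical surface is a gentle height field (±0.8 µm) or a
cylinder (`tube`), so nothing downstream can assume exact flatness.

The renderer draws each junction edge as a 1 µm wall below the apical
surface at 0.6×0.25×0.25 µm voxels, with log-normal per-edge intensity
unevenness (σ = 0.3), 10% of edges carrying a 25% gap, vesicle puncta
below the belt, rare bristle cells at 3× intensity, anisotropic Gaussian
PSF blur (0.5 µm axial / 0.12 µm lateral) and Poisson noise at 200 photons
per intensity unit. These are the nuisance structures described for real
E-cad::GFP imaging; what the renderer does *not* emulate: photobleaching,
depth-dependent attenuation, tissue autofluorescence, motion blur within a
stack, and real PSF side lobes. Passing the end-to-end criteria therefore
shows the pipeline tolerates the modelled nuisances at realistic SNR, not
that the default thresholds transfer to any particular microscope without
the usual per-dataset tuning of `threshold`, `T_E` and the scale interval.

`corrupt_tracks` discards frames to emulate a lower acquisition rate,
re-attributing events by composing the lineage between surviving frames;
with the default mild drift the tracker still scores AF1 = 1.0 at factor
2, so the decimation experiment is reproduced in kind rather than in
degradation magnitude.

## Problem sizes

The test suite and the acceptance script run the standard 50-cell,
10-frame scenario, one rendered volume of ~12×132×132 voxels for the
detection scores, 20³ grids for the Eikonal comparisons, 1000 simulated
tracks for the smoother, and 100 random instances for the tracker oracle —
sizes chosen so the full suite completes in about two minutes while every
claim is still exercised end to end.

## Known limitations

* Face tracing assumes a locally smooth monolayer; strongly folded tissue
  (normals flipping within a cell) would break the rotation system.
* The mitosis union polygon requires the siblings' shared edges to form one
  contiguous run; exotic face pairs fall back to no hypothesis.
* Tracking solves consecutive frame pairs only — no global optimisation
  over all frames, no re-identification across gaps.
* The strain fit is a single affine field per frame; spatially varying
  strain needs windowed fits, which the per-cell velocities support but the
  pipeline does not automate.
* `rotation_acos` is reported for fidelity to the stated convention but is
  not a rate; use `rotation_angle`.
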