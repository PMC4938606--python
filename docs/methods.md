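# Methods

This note documents the models, numerical choices and limitations behind
`lungmotion`, in the order of the processing chain.

## Scope and inputs

The package quantifies respiratory mechanics from (a) a binary 3D lung
segmentation at full expiration (the reference frame, index T) and (b) a
displacement provider mapping reference-frame positions to each of T frames
of an expiration maneuver (full inspiration at frame 1). Estimating the
displacement field itself — e.g. group-wise B-spline registration of a
dynamic MRI sequence — is out of scope; the field is consumed as an input.
For registration pipelines the package supplies the supporting mask
machinery: Otsu thresholding, body-mask construction, the iterative
bias-correction driver (three iterations by default, each re-thresholding
the latest corrected image and re-correcting the *original* image with the
newest mask), mask union + 50 mm dilation to restrict registration, and
Dice overlap for parameter evaluation. The bias corrector is a pluggable
contract; a least-squares polynomial corrector ships for testing, and an N4
backend (SimpleITK, 100 mm initial control-point spacing, two fitting
levels of up to 500 iterations) can be configured where available.

Axis convention, fixed package-wide for a supine subject: x = left–right,
y = anterior–posterior (+y anterior), z = cranial–caudal (+z cranial).

## Surface extraction

Meshes are extracted by marching cubes on the 0.5 level set of the binary
occupancy, linearly resampled to an isotropic pitch equal to the target
edge length (default 4 mm, matching typical dynamic-scan resolution; mean
edge ≈ pitch). The linear resampling acts as an anti-staircase filter;
extra Gaussian smoothing is available but off by default because it shrinks
convex shapes measurably (≈2% volume on a 25 mm sphere at σ = 1 voxel).
The largest connected component is kept; watertightness and outward
orientation are validated at construction. Enclosed volume uses the
divergence theorem over triangles. Known bias: axis-aligned *flat* faces
quantize to half a pitch when the extraction pitch exceeds the native
spacing; curved anatomy does not show this.

Maximal principal curvature κ_max is estimated per vertex by a quadric fit
(with linear terms, which absorbs vertex-normal error) over the 2-ring in a
local tangent frame; the sign is fixed by the outward normal so convex
regions have κ_max > 0. On analytic meshes the estimate is accurate to
<1%; on voxel-derived meshes staircase noise inflates κ_max by tens of
percent — acceptable for the watershed, which only needs ridges to stand
out of plateaus, and the reason quantitative curvature checks use analytic
sphere/cylinder meshes.

## Surface partitioning

1. **Watershed.** Basins grow from local-minimum plateaus of κ_max on the
   vertex graph by an ascending flood (plateaus are flooded as units, so a
   constant field yields a single patch); triangles take the majority basin
   of their vertices, three-way ties going to the basin with the lowest
   mean curvature; patches are split into edge-connected components. No
   curvature pre-smoothing is applied by default: an oversegmented patch
   map makes the subsequent hull-distance rule act locally, which is what
   the costal rule needs.
2. **Costal extraction.** A patch becomes costal when ≥ 25% of its
   triangles lie within 10 mm of the lung's convex hull. Hull distance for
   interior points is the exact minimum over hull-facet planes. Small
   non-costal components (< 0.2% of triangles) are absorbed into the costal
   surface afterwards: they are enclosed slivers that would otherwise
   strand random-walker nodes without seeds.
3. **Edge weights.** On the non-costal triangle-adjacency graph,
   `w_ij = exp(−d_ij²)` with `d_ij = w₁·d̂_ij + w₂‖n_i−n_j‖ + w₃ f(κ_ij)`;
   centroid distances d̂ are normalized by their regional mean so the
   weights are scale-free, and the hinge curvature across an edge is
   `±‖n_i−n_j‖/d̂`, positive for convex hinges (neighbor centroid below the
   tangent plane). All three coefficients default to 1. Weights are floored
   at 1e-12: `exp(−d²)` underflows to exactly zero across degenerate
   hinges, which would disconnect the graph.
4. **Seeds.** The most posterior non-costal patch seeds *diaphragmatic*;
   the most superior patch and every patch with an occluded triangle
   (first hit of the ray from a viewpoint centrally below the lung — at
   (centroid_x, centroid_y, z_min − 0.25·CC extent) — is another triangle,
   with a 4 mm clearance tolerance so grazing rim triangles do not
   self-occlude) seed *medial*. The extreme-position rules ignore patches
   below 0.2% of region area or 5 triangles: a two-triangle rim sliver is
   not "the posterior patch". Labels then propagate between adjacent
   patches whose mean normals diverge < 30° and whose mean inter-patch
   weight exceeds 0.15 (no separating ridge; with mean-normalized distances
   every edge has d ≳ 1, so flat adjacencies sit near exp(−1) ≈ 0.37 and
   ridges far below — 0.15 separates them cleanly), until fixpoint. One
   seed per labeled patch at its central triangle.
5. **Random walker.** Probabilities solve the combinatorial Dirichlet
   problem (sparse Laplacian, direct solve) with seeds clamped; components
   without seeds get uniform probabilities with a warning. Thresholds
   p_diaphragm > 0.8 and p_medial > 0.6 define partitions; each iteration
   adds one random seed per 50 partition triangles (fixed RNG) and stops
   when < 3% of triangles change, or at 10 iterations; if propagation
   already labeled every patch the walker is skipped. Final rule:
   p_diaphragm > 0.8 → diaphragmatic, else medial.

Costal triangles are subdivided into anterior/posterior/superior/lateral by
the bounding-box face their outward normal ray exits (medial hits map to
lateral, inferior to posterior) — visualization labels only.

## Motion features

Volumes are signed mesh volumes per frame. CC size = z(lung apex) −
z(diaphragm apex), both recomputed per frame with partition labels carried
by connectivity; AP size is the whole-lung AP extent. Swept volumes join
each triangle's positions at t and t+1 into a closed prism; side quads are
split along the diagonal attached to the smaller global vertex id, so
prisms sharing a mesh edge have cancelling side faces and the closed-surface
sum telescopes *exactly* (≤1e-10 relative) to V(t)−V(t+1) — the module's
master invariant. Sign convention: inward motion positive, so an expiration
maneuver displaces positive volume. D and C are eroded by two triangle
strips (BFS layers) before accumulation to drop unreliable boundary
triangles.

Excursion: per diaphragmatic triangle, the CC displacement of its centroid
relative to frame 1 at the time of *maximum magnitude*, signed — so
paradoxical caudal motion yields negative values of full size (a plain
signed maximum would report the smallest caudal displacement instead). A4
is the mean weighted by reference-frame triangle areas (held fixed over
time); A5 splits the diaphragm at the mid-coronal plane of the reference
bounding box and reports posterior mean − anterior mean in mm (right lung;
the left is dominated by the cardiac indentation), with both means also
exported so a ratio can be formed.

Orientation: each diaphragm normal is projected onto the sagittal (y–z)
plane; the angle to the caudal axis is positive when the dome is pitched
posterior-low ("tilted backwards"), i.e. angle = atan2(n_y, −n_z) for the
outward (caudal) normal — the convention that makes a healthy inspiratory
dome positive. A6 is the area-weighted mean at frame 1; the start/end of
motion are the first frames reaching 10%/90% of |V(t)−V(1)| (first
crossings, flagged if the volume curve is non-monotone), and A7 is the
signed extremum of orientation(t) − orientation(start) inside that window.

A1/A2 are also emitted normalized by residual volume (A1_rv, A2_rv), since
between-subject comparisons need size compensation; both raw and normalized
variants are kept because the normalization convention varies between
studies.

## Unfolded maps

Each labeled part maps to a side of a rectangular box (diaphragm → bottom,
anterior/posterior costal → front/back, lateral costal split by normal x
sign → left/right; superior costal is not mapped). Sides are
orthographically projected onto their box face and hinged about the shared
bottom edge into the plane — segments tile without overlap. Map values are
per-triangle maximum excursions along the segment's axis with inward motion
positive (cranial for the bottom, toward mid-coronal/mid-sagittal for the
sides). The module emits (segment, triangle, u, v, value) records; any
plotting layer can rasterize them.

## Agreement metrics and group statistics

For two time series of the same measurement, ASE = |f(T) − g(T)| captures
the systematic bias at full expiration and MARE = mean_t |(f−g)(t) −
(f−g)(T)| the residual variation after removing it. Group comparisons use
the two-sided Wilcoxon rank-sum test with the exact null distribution for
groups of ≤10 without ties (normal approximation with tie correction
otherwise); all-tied features report p = 1 with a degeneracy flag. The
feature summary is sorted by descending p; the Pearson matrix masks cells
with p ≥ 0.05 (no multiple-testing correction, by design — the reporting
mirrors common practice for exploratory cohort tables).

## The phantom: what it emulates, and what it does not

The phantom is a lung-shaped closed solid: an ellipsoidal costal shell
(half-axes 58/84/146 mm), a raised diaphragm dome (flat-topped quartic
profile in x, depth 32 mm, with a 46 mm parabolic AP recession), and a
vertical cylindrical pocket on the medial face emulating the deep
cardiac/mediastinal groove (radius 44 mm, floor at z = 60 mm). Two shape
choices deserve explanation: a *spherical* indentation of feasible depth
would put 30–60% of its surface within 10 mm of the convex hull (spherical
zone area is uniform in depth), defeating the convexity-based costal rule
at desk scale, whereas a deep crescent-like groove — which is also what
real mediastinal faces look like — keeps that fraction near 15%; and the
dome must recess toward the AP rims, else the hull hugs the barrel-vault
crest and the diaphragm would classify costal. The ~10 mm band of surface
adjacent to the costophrenic junction ring is genuinely hull-close — on
real-size lungs as at desk scale — and is expected to classify costal;
the partition quality target is therefore formulated as whole-surface
diaphragm-label agreement, not rim-perfect recall.

Motion is an analytically invertible map: posterior-anchored AP scaling
`y' = −ay + (y+ay)·k(t)` plus a vertical shear `z' = z + δ·W(z)` whose
amplitude combines dome descent `d_max·(1−s(t))` (optionally with an AP
gradient) and a tilt schedule θ(t); W(z) is 1 over the dome and tapers
linearly to 0 over 12 mm above it, so apex and upper shell are static. The
tilt term is written against the deformed AP coordinate and the per-frame
tilt-plane coefficient is calibrated (1D root find) so the *area-weighted
mean* sagittal orientation of the dome equals θ(t) exactly — orientation
truth is a property of the generated data, not an approximation. The tilt
schedule holds θ_start for the first quarter of the maneuver and reaches
θ_end by 85% progress, so the 10%/90% volume-change window lies on the
plateaus and the orientation-change truth equals θ_end − θ_start exactly.
An important identity surfaced by the calibration: an AP excursion gradient
*is* an orientation change — the two cannot be prescribed independently,
which is why the stock conditions encode their posterior- or
anterior-dominant excursion through the tilt schedule alone.

Stock conditions (the phantom's study conditions, fixed):

- **control-like** — descent 20 mm, tilt 20°→5° (posterior-dominant
  excursion, A5 > 0), no AP contraction (so CC expansion strictly exceeds
  AP expansion, B6 > 1);
- **patient-like** — descent 2 mm, tilt 3°→5.5° (orientation *rising*
  during exhalation, anterior-dominant excursion, A5 ≤ 0), 15% AP
  contraction (B6 < 1, diaphragm contribution < 0.2);
- **diaphragm-only** — descent 20 mm, flat untilted dome, chest frozen;
- **chest-only** — 15% AP contraction with a perfectly flat dome (zero
  recession): a flat horizontal surface sliding horizontally sweeps exactly
  zero volume, so its diaphragm contribution is identically 0.

The RNG seed jitters the *shape* (axes ±3%, dome/pocket ±5%, pocket center
±3 mm) so seeds give different lungs, while motion parameters stay nominal.
Masks rasterize the exact inverse map on a 2.5 mm grid by default (≈70³
voxels, ≈20–25k triangles at 3 mm edge — sizes chosen so the full pipeline
runs in seconds per phantom); truth curves and area-weighted features come
from column quadrature of the analytic geometry (exact in z, second-order
transversally, 1 mm step).

What the phantom does **not** emulate: MRI intensity, ghosting and other
artifacts; registration error in the displacement field (the provider is
exact, so feature-recovery results bound discretization error only, not
registration error); lobar fissures, airways, or a second lung; hysteresis
or non-monotone breathing. Passing tests demonstrate the measurement chain
is correct given a faithful displacement field — not that any registration
method supplies one.

Kinematics recovery checks use the analytic surface labels rather than the
measured partition, deliberately: partition quality is assessed separately
(diaphragm-label agreement ≥ 90% over five phantom seeds), and conflating
the two would make feature-recovery failures unattributable. With the
measured partition, costal-boundary leakage mostly affects the swept-volume
split (A1–A3), as the README's worked example shows.

## Numerical choices and degenerate inputs

- Otsu: 256 bins over [min, max]; variance-flat valleys tie-break toward
  the lower cut. Constant volumes are rejected.
- Dice of two empty masks is defined as 1 (total function, documented).
- Empty diaphragm regions mark CC-based features missing (NaN + warning);
  left-lung A5 is NaN (not applicable).
- The walker reports non-convergence (flag in the partition report) after
  10 iterations and returns the last state.
- All RNG use (walker re-seeding, phantom jitter) flows from explicit
  seeds; the full pipeline is bitwise reproducible.

## Known limitations

- The curvature estimator is noise-limited on voxel meshes; features that
  depend on it only through the watershed are robust, but κ_max values
  themselves should not be interpreted quantitatively there.
- The costophrenic rim band (~10 mm) classifies costal by construction of
  the hull rule; diaphragm areas are mildly underestimated and swept-volume
  splits from the *measured* partition inherit that bias.
- Extremum-based sizes (CC, AP) carry ≈ half-voxel noise; ratio features
  (B4, B5) are accurate to ≈1% at 1.5 mm spacing and ≈2% at 2.5 mm.
- A5 is reported as a difference in mm (posterior − anterior), with both
  means exported; some studies report a ratio instead.
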