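# Methods

`voxcyto` implements a detect-then-segment pipeline for 3-D cytometry of
densely packed, roughly spherical nuclei (the motivating system is the
proliferative zone of the *C. elegans* germ line, with variants for mouse
olfactory epithelium and pre-implantation embryos), together with a
synthetic phantom generator that provides full ground truth for every
stage. This note records the models, the numerical choices, and what the
phantom does and does not establish about real data.

## Coordinate conventions

Voxel grids are indexed `(x, y, z)`, 0-based; physical positions are
`index * spacing` in μm (voxel-centre convention). All distances
(matching radii, suppression radii, truncation radii, geodesic
positions) are Euclidean in μm, honouring anisotropic spacing. TIFF
pages run along z; label TIFFs store the cell index as the pixel value.

## Phantom generator

Cells are modelled as a nucleus (ball of radius *r*, default mean
1.5 μm ± 10 %) surrounded by a cytoplasmic rim; the cell radius is
1.3 *r*. Overlaps between packed cells are resolved by the additively
weighted nearest rule `argmin(d − r_cell)`, so larger cells push shared
boundaries beyond the midpoint as real packed cells do. Arrangements:
`tube` (cells in a cylinder along x, minimum separation 1.6 *r*),
`grid` (a jittered lattice that tiles the whole volume — used for
segmentation benchmarks so every boundary has a competing neighbour
behind it, as in tissue), and `scatter`.

Channels:

* **DNA** — phase-dependent chromatin texture. G1: a dim peripheral
  shell plus 5–6 fine chromocenters (σ 0.25 μm); S: dispersed
  (uniformly filled) chromatin whose occupied radius grows with
  content; G2: shell plus 8–12 larger clumps (σ 0.45 μm); M: a compact
  condensed core. Shell thickness scales with DNA content at constant
  peak brightness, so per-voxel intensity percentiles are
  content-neutral (as for a real stain, where more DNA occupies more
  volume) while the per-cell *sum* is exactly proportional to the true
  content (2C in G1, 4C in G2/M, uniform 2–4C in S) before attenuation
  and noise.
* **Membrane** — bright sheets on cell boundaries, a fainter
  nuclear-envelope shell at the nuclear radius (amplitude 0.25), and
  fine-scale rectified band-passed clutter inside cells (amplitude 0.4,
  correlation 0.4 μm) modelling cytoplasmic membranous organelles.
  Both confounds matter: segmentation robustness claims would be
  trivially optimistic on clutter-free interiors.
* **EdU** — uniform nuclear signal in S-phase cells.

All channels pass through a 0.15 μm Gaussian optical blur, exponential
z-attenuation (default 0.03/μm) and additive Gaussian noise whose σ is
relative to the 90th-percentile foreground level (σ relative to the
absolute maximum would be dominated by rare bright puncta). The default
phase mix is G1/S/G2/M = 0.20/0.45/0.30/0.05; mitosis is short, so
M-phase cells are rare in cycling tissue. Everything is deterministic
given the spec's seed.

What the phantom does **not** model: realistic PSF anisotropy and
diffraction rings, meiotic/crescent nuclear morphologies, spatial
cell-cycle gradients, stage drift, or spectral bleed-through. Passing
recovery tests on phantoms therefore demonstrates correctness of the
computations under controlled conditions, not performance on any
particular real dataset.

Seed jitter draws displacements uniformly from a ball (rejection
sampling; the mean displacement magnitude is 3ρ/4). Guide degradation
follows the crop → invert → clamp at 0.85 → min-max rescale → tile →
multiply recipe; the crop location and kernel size are parameters
(default 108×108×40 voxels; the benchmark uses a 30×30×16 kernel sized
to its phantom).

## Guide images

The membrane route: (1) sharpening — each voxel is divided by the mean
of a 2-D sliding square (side = cell diameter) in its xy-plane, which
cancels per-plane gain; the local mean is floored at half the global
mean so structures bordering empty background are not amplified far
beyond structures inside dense tissue; (2) Gaussian blur with σ =
membrane thickness; (3) sheet enhancement from the Hessian's ordered
eigenvalues d1 ≤ d2 ≤ d3 via `I′ = −d1·exp(−(d2/2d1)²)·exp(−(d3/2d1)²)`
for d1 < 0 (bright-sheet convention; derivatives are central
differences on the μm grid, so the anisotropic z-step is honoured);
(4) final blur, then a robust rescale by the 99th percentile with
clipping, so boundary sheets saturate uniformly rather than being
normalized against a few exceptionally bright voxels.

The DNA route (embryo-style): local mean DNA values in small windows
around detections are fitted to `m(x,y,z) = exp(c1 z)(c2 x + c3 y + c4)`
by nonlinear least squares (seeded from a log-linear estimate of the z
trend — the model is multiplicative in z but additive in x,y, so pure
log-linearization is invalid); the image is thresholded at `k·m` with
k = 1/3 by default, median filtered, inverted and blurred. Degenerate
fits fall back to the constant model with a warning.

## Cell detection

Features per window: xy-slice mean brightness plus
histogram-of-oriented-gradients blocks over a 4×4 grid of
non-overlapping sub-windows in the xy and xz slices through the
candidate centre. Gradients are full-volume central differences; each
pixel votes its magnitude into one of 18 signed-orientation bins; each
sub-window histogram is L2-normalized with the norm appended as an
extra feature (609 features for the default geometry; window = 2× the
cell diameter). Dense scanning computes exactly the same features at
every voxel via per-bin integral images, so windowed and dense scores
agree to machine precision; windows crossing the volume border are
zero-padded.

Training: linear SVM (hinge loss, no intercept — the decision rule is
`w·v > τ` with τ applied post hoc, so precision–recall sweeps need no
retraining). Positives are symmetrized by axis flips. Negatives (any
voxel farther than one cell radius from every labelled centre) are
hard-mined: train on a random subset, densely scan, add the
highest-scoring margin violators, repeat until none remain — at
convergence this reaches the same optimum as training on every negative
at once, which a test asserts (cosine similarity of the weight vectors
> 0.999). Two latent re-centring passes then move each labelled centre
to the detector-response maximum within half a cell radius and retrain.
Scanning runs at 5 geometric scales over 0.7–1.5 (the image is
rescaled, not the window); responses above τ that are local maxima of
the score volume are kept, mapped back to μm, and greedily suppressed
within one cell radius of any higher-scoring detection.

## Segmentation

**Active contours.** One level-set field per cell, mask = {φ < 0},
evolved under `dφ/dt = −g‖∇φ‖(1 − c1 k) + c2 ∇g·∇φ` with mean curvature
`k = ∇·(∇φ/‖∇φ‖)`: an outward motion term with edge-stopping speed g, a
curvature penalty, and an advection term transporting the contour along
`−c2∇g` (with c2 < 0 contours are pushed back as they approach a
boundary from inside; with c2 > 0 they are pulled onto it from either
side). Phase 1 (conservative): c1 = 0.1, c2 = −1, 650 steps of dt =
0.15; phase 2 (refinement): c2 = +1, 300 steps. φ is initialized as the
signed distance to a 1-voxel ball at each seed and evolved in a cropped
sub-window (margin 2× the cell radius) within a narrow band (half-width
5 voxels), with signed-distance reinitialization every 50 steps, upwind
(Godunov) differencing for the motion term and upwind advection.

Numerical conventions that make this robust at the scale of a few
voxels per cell: the PDE is integrated on the voxel-normalized grid
(lengths in units of the smallest voxel side, per-axis scale factors
for anisotropy) — this is the scale on which the canonical parameter
values balance the motion and advection terms; the speed map is the
inverted guide after *local max-normalization* (each voxel's guide
value is divided by the local maximum within ~2 cell diameters) and
*saturation* (any relative level ≥ 0.5 is a full stop), so the stopping
condition depends on boundary strength relative to nearby boundaries
and is invariant to slowly varying, multiplicative staining efficiency —
the property that makes the method robust to degraded guides; the
advection field uses the raw inverted guide so refinement can still
pull the contour onto the boundary crest inside the saturated band.
Masks may never overlap: a voxel claimed by two cells is frozen for
both fields (the later claimant is reverted), so packed neighbours
block each other's leaks.

**Truncated Voronoi** (baseline): voxel ∈ cell i iff nearest seed (μm
metric) is i and within radius r; exact ties go to the lower index.
Uses no guide.

**Marker-controlled watershed** (baseline): minima imposed at the seed
voxels (marker flooding), the guide flooded, and segments with voxel
counts outside 5–500 % of the median relabelled to background.

## Evaluation

Detections match annotations under the radius rule (default 1.5 μm,
about one cell radius): each annotated centre takes its nearest
detection within the radius, greedily by distance so each detection
matches at most once; remaining detections are false positives,
unmatched centres false negatives. AP is the un-interpolated area under
the precision–recall curve swept over all distinct scores. Segmentation
accuracy: pairwise Jaccard (intersection over union), aggregated by the
Hungarian-optimal one-to-one matching maximizing total Jaccard; AO is
the mean Jaccard over matched pairs (zero-overlap pairs are not
matched). Segment-level precision/recall count matched pairs with
Jaccard ≥ 0.5 (a documented stand-in; the threshold is a parameter).

## Quantification

*Top-layeredness* θ: the fraction of a cell's xy-footprint columns in
which that cell is the first nonzero label along z (objective above the
stack at z = 0; direction is a flag). θ = 1 means direct line of sight;
cells with θ > 0.1 are "top layer".

*Position*: a simplified principal curve (iterated Gaussian-weighted
local-averaging polyline seeded from the leading principal axis, end
segments extrapolated) gives each cell an arc-length distance from the
annotated distal end; cell rows are 1 + breadth-first hops from the
distal cell on the touching-masks graph (6-connectivity face
adjacency). Cells on disconnected components are flagged; the DNA
recipe gives them pseudo-rows interpolated from the row-vs-geodesic
trend of reachable cells.

*DNA content (germline recipe)*: keep top-layer cells; fit a cubic
smoothing spline (scipy's default smoothing heuristic; linear fallback
under 4 support points) of the per-cell 95th-percentile DNA value
against geodesic distance and divide raw sums by it (distal-axis gain
correction); within each 4-cell-row bin, affinely map the 10th/85th
percentiles of normalized content to 2C/4C. Bins under 5 cells merge
with a neighbour. The binning assumes each spatial bin holds a similar
phase mixture — the assumption that lets data pool across specimens.

*DNA content (epithelium recipe)*: quadratic fit to the per-x-slice
90th-percentile intensity and linear fit over the middle 25 z-slices
correct the two gain axes; per-cell sums are scaled so the median
annotated M-phase content is exactly 4C. Absence of M-phase annotations
is an error (the normalization anchor is missing).

*EdU*: median filter; clamp into [t1, t2]; rescale to [0, 1]; per-mask
sums; affine map of the 10th/85th content percentiles to 0/1; a manual
threshold (default 0.5) gives ± status. *Phase rule*: EdU+ → S; EdU−
with C < 3 → G1 (the 2C/4C midpoint, a parameter); EdU− with C ≥ 3 →
G2/M; manual M annotations override. Phase indices are per-bin
proportions; a categorical chi-square compares two bins.

All normalizations are invariant to global multiplicative gain of their
input channel.

## Morphology classifiers

Per cell: a 2-D DNA patch at the mask's median-z slice, masked to the
cell, clipped to 34×34 px centred on the centroid. Features: the number
of connected components and pixel count of the exact-Otsu-thresholded
foreground (the threshold maximizes between-class variance by
exhaustive search over unique values, well-defined on float data), plus
centre-surround Haar responses (inner-square mean minus surround-ring
mean, via integral images). The frozen enumeration convention — outer
square side 3..8 px with the inner square exactly two pixels smaller (a
one-pixel ring), at every position — yields exactly 5239 features in a
34×34 frame; alternative conventions (`parity`, `odd`) are selectable
and give 10006 and 5176.

One linear SVM per phase (one-vs-rest) with per-phase hyperparameters
(box constraints 1e-5/1e-3/1e-2/1e-3 and tolerances 1e-7/1e-8/1e-8/1e-8
for G1/S/G2/M, ≤ 150 000 iterations), class-balanced box-constraint
rescaling, and three deliberate design choices at this feature/data
scale: features are scaled per block (the two count features
individually, the Haar block by one pooled standard deviation —
per-feature z-scoring inflates pure-noise Haar dimensions to the same
variance as signal dimensions and buries it); patches are centred in
the Haar frame so positional features are comparable across cells; and
each classifier's decision threshold is calibrated for balanced
accuracy on 3-fold out-of-fold scores within the training split (the
learned direction is untouched — tiny box constraints otherwise leave
degenerate intercepts). Statistics (sensitivity/specificity per phase)
are means over 25 random 50/50 splits. Morphology phantoms are sampled
at 0.1 μm in xy so a 34×34 patch holds a ~30 px nucleus; at 0.3 μm
sampling chromocenters fall below the resolution floor and no
classifier can see them.

## Benchmarks

The segmenter grid runs all three segmenters on identical packed-grid
phantoms under clean/degraded guides and seed jitter of 0/0.5/1 μm, and
reports AO with relative decreases against each segmenter's
clean/zero-jitter baseline. Only orderings and relative magnitudes are
asserted — under ideal conditions all three agree to within 0.1 AO;
degradation hurts watershed (whose flood ordering is scrambled by
absolute-intensity distortions) several times more than active contours
(whose ratio-based stopping is locally scale-invariant and whose
collisions block leaks); jitter hurts truncated Voronoi (which trusts
the seed positions geometrically) far more than active contours (which
re-converge to the boundaries). Absolute AO values depend on the
phantom's stain model and are not comparable to values measured on real
stacks. The detector learning curve trains on resampled subsets of a
phantom pool and reports AP versus training-set size.

## Problem sizes

Default study sizes keep every stage exact but small: 30-cell tubes
(96×48×32 voxels) for detection, a 48-cell packed grid (32×32×24) for
segmentation benchmarks, a 200-cell tube (480×48×32) for the
quantification recipes, and 600 patches from fifteen 40-cell phantoms
for the morphology classifiers.
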