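# Methods

morphodyn quantifies the morphodynamics of highly deformable cells in 2D
time-lapse fluorescence microscopy: it segments the cell in every frame,
establishes sub-pixel point correspondences between consecutive cell
outlines, samples fluorescence in the cortical band just inside the
membrane, and assembles the results into spatio-temporal maps (frames x
boundary positions) of motility, fluorescence and boundary convexity.
This note records the models, the numerical choices, and the limits of
what the synthetic validation shows.

## Coordinate and orientation conventions

A point is `(x, y)` with `x` the column index increasing rightward and `y`
the row index increasing downward; pixel centers sit at integer
coordinates.  A contour is counter-clockwise (CCW) when its shoelace signed
area is positive in this frame, which places the cell interior on the left
of the direction of travel.  All outlines are normalised to CCW on
construction; outward normals, turning angles and the expansion/retraction
sign convention all derive from this single choice.

## Mask/contour geometry

Masks are traced along the edges of the foreground pixel squares ("crack"
boundary): vertices sit at half-integer corners and collinear runs are
merged.  The traced polygon encloses exactly the foreground pixel centers,
so its shoelace area equals the pixel count and mask -> contour -> mask is
an exact identity for 4-connected hole-free masks (holes are filled on
ingest and logged).  Rasterisation uses the even-odd rule with
centers-on-edge counted as foreground — deterministic and conservative
toward the cell.

Resampling distributes nodes uniformly in arc length along the polygon and
interpolates per-node attributes linearly.  Local convexity is the turning
angle per unit arc length, smoothed with a mass-conserving circular kernel:
node j's turning angle `theta_j` is distributed as `theta_j / D_j` to every
node in its window, `D_j` the window's total arc mass.  This makes the map
value an intuitive local curvature (`1/r` on a circle, negative in
concavities) while the integral `sum_i kappa_i ds_i` remains exactly the
total turning `+2*pi` of a simple CCW polygon — the invariant the tests and
the convexity map rows check.

## Active contour (snake)

The per-frame snake evolves N nodes with velocity `v <- mu*v + F`,
`mu = f_friction` in (0, 1], and three forces:

- tension `f_tension * (neighbour midpoint - node)`;
- contraction `f_contraction * (unit vector toward the centroid)`;
- image force `f_image * tanh((I(node) - threshold) / w) * n_hat`, `n_hat`
  the outward normal, `I` the bilinearly interpolated intensity of the
  frame pre-smoothed with a Gaussian (`presmooth_sigma`, default 1 px), and
  `w = edge_softness * robust range` (default 0.25 of the 1st-99th
  percentile range).

The smooth tanh activation (rather than a hard on/off switch at the
threshold) is deliberate: with a hard switch the node update near a sharp
edge has an effective stiffness of `f_image * dI/dx` per intensity unit of
transition, far beyond the damping margin of the update map, and the snake
orbits the boundary instead of settling.  With the tanh transition the
fixed point is attracting and the boundary settles where the interpolated
intensity crosses the threshold (shifted outward by the tiny offset where
the image force balances the contraction).  Every 100 iterations the
velocities are zeroed — residual kinetic limit cycles around the force
balance then decay instead of orbiting forever.  Convergence is declared
when the maximum node displacement per iteration falls below
`convergence_eps_px` (default 0.01 px); evolution also stops, flagged
not-converged and logged, when the displacement has not improved for
`stall_iterations` (default 400) — on noisy frames the equilibrium jitter
can exceed the eps without the outline being wrong.

Node spacing is kept in [0.5, 1.5] x `node_spacing_px` by midpoint
insertion and short-edge deletion (lowest index first); crossing edge
pairs are excised each iteration (shorter loop removed).  An enclosed area
below 4 px^2 raises a collapse error carrying the frame index and the
outlines of the frames already segmented.  If no threshold is given, the
midpoint of the frame's robust intensity range is used — this is the
"unsupervised" mode used in the end-to-end validation, and deliberately
so: a single global threshold cannot fit both the bright and the dim side
of a polarised cell, which is precisely the failure mode the random-walk
refinement repairs.

Defaults: `node_spacing_px` 4, `f_image` 0.3, `f_contraction` 0.04,
`f_tension` 0.01, `f_friction` 0.6, `max_iterations` 4000.

## Random walker and locally adaptive weights

Segmentation solves the discrete Dirichlet problem on the 4-connected
pixel graph: foreground probability 1 on foreground seeds, 0 on background
seeds, harmonic elsewhere with Gaussian edge weights
`w_ij = exp(-beta * d_ij^2)`.  The system is solved by direct sparse
factorisation (residual below 1e-8 by construction; a conjugate-gradient
path would be appropriate above ~1e6 unseeded pixels, beyond the image
sizes this package targets).

The *plain* weighting normalises `d_ij = (g_i - g_j) / G` with `G` the
robust global range (99th - 1st percentile).  The *locally adaptive*
weighting normalises by a robust local scale:

    s(p) = median over the window of the mean absolute neighbour
           difference, divided by 0.954 (Gaussian consistency)
    d_ij = (g_i - g_j) / (s_ij + eps) * (s_ref / G)

with `s_ij` the average scale of the two pixels, `eps = 1e-3 * G`, and
`s_ref` the image-median scale.  Three properties motivate this exact
form.  The median (not the standard deviation) means a genuine boundary
crossing the window — a minority of its pixels — does not inflate the
local scale, so real edges keep their full contrast.  The `s_ref / G`
rescaling puts adaptive and plain differences on one numeric scale: where
the local spread equals the typical spread the two weightings coincide,
so a single beta (default 90) is meaningful for both.  And the whole
expression is exactly invariant under affine intensity rescaling
`g -> a*g + b`.

What adaptivity buys: in fluorescence imaging the noise is
signal-dependent (shot noise grows with brightness), so the bright front
of a polarised cell carries intensity steps that global normalisation
mistakes for edges, while its dim rear boundary is weak on the global
scale.  Local normalisation equalises both — the measured head-to-head on
the gradient-disk phantom (intensity halving across the cell, Poisson-
scaled noise) shows the adaptive Dice strictly above the plain Dice at
matched beta.  With spatially uniform Gaussian noise the two weightings
are nearly equivalent by construction, and the phantom reflects that.

The mask is the probability field thresholded at 0.5, keeping every
4-connected component containing a foreground seed (so all foreground
seeds are honoured) with holes filled.  The pipeline's *outline*, however,
is extracted from the probability field itself at the 0.5 iso-level by
marching squares — sub-pixel, which roughly halves the boundary error
relative to tracing the binary mask — then smoothed (running mean, window
5) and resampled to 2 px node spacing.  If the level set is open or
degenerate the mask trace is the fallback.

## Shape-preserving seeding

Seeds are generated from a prior mask by vector offsetting of the traced
contour: foreground = pixels inside the contour contracted by `d_fg`
(default 8 px), background = pixels outside the contour expanded by `d_bg`
(default 10 px) — both of the order of a cortical band.  Plain polygon
buffering implements the offsets exactly (0.2 px RMS on analytic circles),
but inward buffering deletes any part of the cell thinner than `2*d_fg` —
exactly the pseudopodia and filopodia one most wants to keep.  The
contraction therefore retains a *spine*: the homotopic skeleton of the
rasterised cell, restricted to pixels whose boundary distance is below the
offset (those the plain offset would delete, plus a 1.5 px overlap band
for attachment), buffered to ~1.4 px width and unioned into the offset
body.  Thinning-based skeletonisation is used rather than the exact medial
axis because it is robust to boundary rasterisation ripple (the medial
axis of a rasterised disk sprouts long spurious branches; its thinned
skeleton is a point).  On the finger phantom (3-px-wide process, 4-px
contraction) this keeps foreground seeds inside the finger where disk
erosion keeps none.  If the contraction empties the cell entirely, the
mask skeleton becomes the foreground seed set (logged).

The per-point offset distance bound (within 10% of the nominal distance)
holds away from thin features; on a retained spine the distance is by
design smaller — that is the point of keeping it.

## Electrostatic contour migration (ECMM)

Edge tracking maps every node of the outline at frame t to a point on the
outline at t+1 by advecting it along the electric field of positive unit
charges spread along the source contour and negative charges along the
target (1/r kernel, >= 4 charges per px of arc, placed at arc midpoints so
a node on its own contour sits symmetrically between charges).  Field
lines of this configuration do not cross, so the correspondence is
order-preserving, and it approximately minimises the summed path length —
the deformation energy.  The 2D shell property of the 1/r kernel makes
both directions work: between nested contours the inner contour's interior
field vanishes, leaving only the force toward the target.

Advection is explicit with fixed steps of 0.05 px along the normalised
field; the landing is the first crossing of a step segment with the target
polygon (first crossing wins).  A *capture radius* of half a step catches
two degenerate geometries: nodes already on the target land immediately
with path length ~0, and nodes skimming along a locally static boundary —
where the near-cancelling dipole field is tangential — are landed at their
nearest target point instead of sliding along it and accruing phantom path
length.  Nodes that fail to cross within the step budget are mapped to the
nearest target point and flagged; so are nodes whose path exceeds three
times their straight-line displacement plus 2 px ("wild paths", nodes that
fell onto a field-line separatrix in a deep cleft — their path length is
not a meaningful local motility).  Flagged nodes appear as NaN in the
motility map; everything else is computed normally.

The step/density defaults (0.05 px, 4 charges/px) were set by the
concentric-circle benchmark: at coarser settings the discrete-charge
near-field zigzag inflates per-node path lengths beyond the +-0.05 px
accuracy the analytic cases demand (measured 4.08 mean / 0.13 max
deviation at 0.1 px and 1 charge/px, against 4.01 / 0.04 at the defaults).

Sign convention: +1 (expansion/protrusion) when the landing lies outside
the source polygon, -1 (retraction) otherwise.  For rigid translation the
signed sum over the contour does not vanish exactly: it carries the
second-order term `-(1/2) * closed-integral of d^2 * kappa ds`, about
-14 px^2-equivalent for a 3 px shift regardless of radius, so the
"near-zero signed sum" property is checked in the d << r regime (r = 30,
d = 3, measured ratio ~4%).

## Cortical sampling and spatio-temporal maps

Each node of an outline owns the quadrilateral between its arc segment
(incident-edge midpoints) and that segment displaced inward along the node
normals by the cortex width (default 8 px).  The quad is integrated by
midpoint-rule bilinear sampling weighted by the local area element, so
`sum(node mean * node band area)` reproduces the band integral of the
intensity (within 3% on analytic annuli; the per-node band areas, not
`arc * width`, are used for the total because the inner arc of a curved
band is genuinely shorter than the outer).  Where the cell is thinner than
twice the band, the depth is truncated at half the local chord and
flagged.

Maps are frames x R boundary positions (R default 400).  Each frame's
outline is resampled to R positions; the origin (column 0) of frame t+1 is
the ECMM landing of frame t's origin, so a column follows the same
boundary material and the position axis does not drift when the cell
rotates.  Motility(t, r) is the signed ECMM path length of position r's
own migration divided by the frame interval (px/frame; the motility map
has T-1 rows, one per transition); fluorescence is the cortical sample;
convexity the local curvature.  Registration can only track rotation the
shape itself reveals: with pronounced pseudopods (the rotating-patch
fixture uses 40% amplitude, 0.25 rad half-width) the material patch stays
within 2 columns of 90 over 20 frames while the unregistered axis drifts
by the full rotation; a featureless rotating circle is untrackable by any
shape-based method, and ECMM's minimal-deformation correspondence
correctly reports no tangential motion for shallow bumps.

## DIC reconstruction

DIC contrast is modelled as the directional derivative of the specimen
along the shear axis.  Reconstruction rotates the image so shear lines
become rows (bilinear, with a validity mask so the padding does not bias
the line means), subtracts each line's mean, applies the first-order
recursion `y[n] = decay * y[n-1] + x[n]` (decay default 0.98, in (0, 1)),
rotates back and rescales to the input range.  In the decay -> 1 limit
this inverts the derivative (Pearson r >= 0.9 against the phantom at
decay 0.995, at any shear angle); smaller decay localises the integral and
bounds streaking.  The operation is linear in the input before the final
normalisation.

## Workflow container and I/O

Analysis state lives in one JSON document: format version, per-stage
parameters, per-cell per-frame outlines (`[[x, y], ...]`, pixel units,
origin at the center of pixel (0,0), 0-based frames), ECMM mappings, maps
and provenance.  Unknown keys survive read-modify-write untouched; numbers
are serialised as shortest-round-trip doubles so coordinates are
bit-stable.  The schema (documented in `docs/qconf-schema.md`) is this
package's own; byte compatibility with other tools' containers is not
claimed.  Stacks are single- or multi-page grayscale TIFF (8/16-bit;
RGB/float accepted with a warning), with pixel size and frame interval
from ImageJ-style metadata when present and 1.0 otherwise (logged).  CSV
exports are RFC-4180 with a header row and deterministic order.

## Synthetic movies and what passing tests show

The generator renders a star-shaped cell `r(theta, t) = R(t) * (1 + amp *
sum_k bump(theta - phi_k(t)))` with smooth compact cosine bumps whose
phases advect with rotation, optional translation and radial growth, an
interior intensity with an optional linear ramp anchored at the cell's
left edge (the gradient-cell preset halves the intensity across the cell),
an optional membrane band, and Gaussian read noise (default 9.5 a.u., 5%
of the 190 a.u. dynamic range) plus optional Poisson-scaled shot noise
(the gradient preset uses gain 4 a.u./photon).  A single integer seed
drives all randomness; identical seeds give bit-identical stacks.  Because
theta is the material coordinate, outlines, correspondences, motility and
convexity are known exactly.

The end-to-end validation (20 frames, radius 30 px, 20% protrusions,
halving gradient, 5%-range noise, rotation 3 deg/frame, translation
(1, 0.5) px/frame, image 128^2) recovers the boundary to ~0.5 px mean
Hausdorff and the motility map to ~0.2 px/frame RMSE, and on the highly
deformable variant (40% protrusions, deep concave clefts) the combined
AC+RW pipeline beats the unsupervised snake alone on every frame.  These
movies deliberately idealise: no photobleaching, no defocus or PSF blur,
no touching neighbour cells, no topological changes, and the intensity
model inside the cell is piecewise smooth.  Passing them demonstrates the
algorithms' correctness and sub-pixel calibration, not performance on any
particular real dataset; problem sizes (128^2 images, 10-20 frames,
R = 60-180 map positions) were chosen as the smallest that exercise every
regime the method distinguishes.

## Known limitations

- Single cell per frame; contact resolution, splits and merges are out of
  scope, as are 3D contours and multi-label (>2 class) walkers.
- ECMM reports normal-motion correspondences; purely tangential boundary
  flow on a featureless contour is unobservable to it (and to any
  shape-only tracker).
- The DIC module is conformance-defined by the phantom-inversion property;
  per-image shear-angle estimation is not attempted.
- The snake's default force weights suit bright-cell-on-dark-background
  fluorescence at the synthetic contrast; strongly textured interiors may
  need a larger `presmooth_sigma` or an explicit threshold.
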