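# Methods

This note documents the models and numerical choices behind
`wingforge`, in the order the pipeline runs them.

## Input model and coordinate convention

The primary input is a binary raster: black pixels (value 0) form the
border network — the outline of the domain and the walls between its
subdomains — and white pixels (value 1) are interior or exterior.
Grayscale inputs are thresholded at 0.5 by default (anti-aliased scans
must resolve deterministically; the threshold is a flag), and colour
images are reduced to Rec. 601 luminance first.  Border lines may be
any width; one pixel is enough because region growth is 4-connected
while any 8-connected black curve already separates 4-connected white
regions.

All geometry uses one planar frame: a pixel at `(row, col)` sits at
`x = col`, `y = (n_rows − 1) − row`, pixel centres on the integer
lattice, y increasing upward so exported models display upright in FE
viewers.  Distances are in pixel units throughout; the exporter's
`scale` option converts to physical units per pixel.

## Region detection (burning algorithm)

Region growth is frontier-by-frontier: each pass inspects the four
orthogonal neighbours of the white pixels found in the previous pass,
labels new white pixels as part of the region, and records black
neighbours as its boundary, until no new white pixel appears.  This is
exactly a 4-connected flood fill with boundary extraction, and the
test-suite holds it to bit-identical agreement with
`scipy.ndimage.label` on hundreds of random images.  Visited state is
an integer label matrix rather than re-colouring pixels; the semantics
(no reselection) are identical.

The exterior is burned first, seeded from every white frame-edge pixel
— deterministic, and requiring no user input.  Each subdomain seed and
hole seed then burns its component.  Three conditions abort with
specific errors rather than guessing: a seed whose component touches
the frame (the outline is not closed — silently closing it would
fabricate geometry), two seeds in one component, and a white component
no burn reached (an unseeded cavity would otherwise silently become
"outside").  Holes get negative labels (−2, −3, …) so one matrix holds
the whole partition.

## Signed distance and sizing

The meshable union is: all subdomain pixels, all hole pixels, and the
internal border walls.  Holes are deliberately inside — the method
meshes through discontinuities and removes their elements afterwards,
which is what makes many-hole geometries tractable.  Only the outer
wall (border pixels adjacent to the exterior) is the zero level set.

`d` at pixel centres is the exact Euclidean distance transform: for an
outside pixel, the distance to the nearest inside pixel centre, and the
negated converse for an inside pixel; between centres it is bilinear,
and beyond the frame it grows by the Euclidean overshoot so stray
points always see increasing positive values.  This is the documented,
testable contract (it equals a brute-force all-pairs minimisation
exactly).

One subtlety matters for meshing: the exact-EDT profile jumps from +1
to −1 across the one-pixel in/out interface, so its bilinear gradient
is locally 2, and Newton projection onto the zero set becomes
inaccurate exactly where it is needed most.  The mesh generator
therefore uses an internal variant with every grid value shrunk half a
pixel toward zero — a 1-Lipschitz field with the same sign pattern
whose zero level set differs by under half a pixel — for all of its
decisions, while the public field keeps the exact-EDT values.

Sizing is relative: `h = 1` (uniform, the default) or
`h = 1 + g·|d|` (graded, `g = 0.3`) which concentrates elements near
borders.  `h0`, the absolute node spacing, defaults to 8 px.  A value
of 1 px — the minimum meaningful spacing on a pixel grid — produces
pixel-scale elements and is rarely what a shell analysis needs, hence
the coarser default; `h0 < 1` is rejected.

## Fixed points

Subdomain interfaces must be traced by element edges, so interface
pixels are pinned as mesh nodes, thinned greedily in row-major order to
the mesh spacing.  Junction pixels — walls meeting three or more
regions, or interface endpoints at the outline (detected over the
8-neighbourhood, with the outer wall counting as one pseudo-region) —
are placed first and thinned only at half spacing, so wall topology
survives thinning.

The outline itself is pinned too: the zero level set is traced by
marching squares, sharp corners (tangent turn > 60° within a few
pixels; staircase noise stays below) are located by intersecting the
flanking tangent lines and kept first, and a greedy walk pins a point
wherever the contour runs farther than 0.8·spacing from every existing
pin.  Pinning the outline treats every boundary pixel the burn found as
a fixed point, thinned to mesh density.  It is load-bearing for mesh
quality: without it, outline corners oscillate for ever under force
equilibrium (the classic reason square domains get their corners fixed)
and rasterized arcs emit collinear boundary slivers.

## Mesh generation

The generator is the standard force-equilibrium Delaunay iteration:
equilateral initial lattice of spacing `h0` clipped to the domain and
rejection-thinned with probability ∝ `1/h²` (seeded generator;
reproducibility is a hard requirement, so the initial layout is
deterministic given `rng_seed`); Delaunay re-triangulation whenever any
node has drifted more than `ttol·h0`; per-edge repulsive force
`F = max(L0 − L, 0)` with
`L0 = h(mid)·Fscale·sqrt(ΣL²/Σh²)`; explicit pseudo-time stepping
(`dt = 0.2`); escapees projected back along the numerical gradient of
`d` (central differences at `sqrt(eps)·h0`).  `Fscale = 1.2`,
`dptol = 0.001`, `ttol = 0.1`, `geps = 0.001·h0` are the standard
constants of this scheme.

Three adaptations make it robust on rasterized geometry:

* **Convergence is measured on the net per-iteration displacement**
  (movement after projection).  A corner node that the forces push out
  and the projection puts straight back is in constrained equilibrium;
  measuring the raw force step would report it as eternally moving.
* **Stall cooling.**  If the maximum displacement has not improved for
  50 iterations, `dt` is multiplied by 0.7 (floor: 1% of its initial
  value).  Staircase pixels produce small limit cycles whose amplitude
  is proportional to `dt`; cooling lets them fall below tolerance
  without loosening the tolerance itself.
* **Density control.**  Every 30 iterations, points on bars compressed
  below half their target length are deleted (repulsive-only forces
  cannot clear tangential crowding) and the mesh re-triangulated.

Fixed points within one pixel of the boundary (interface endpoints sit
half a pixel inside it) are snapped onto the zero level set before
meshing — at their original position they trap near-degenerate
triangles between themselves and the projected boundary nodes.  The
snap is bounded by the pin's own distance to the boundary (≤ ~2 px in
the worst junction-wiggle case); interior pins are never moved and
appear verbatim in the output.

After convergence the final Delaunay pass drops outside triangles and
then repairs boundary artifacts: near-zero-area caps (quality < 0.3,
all vertices and centroid within a pixel of the boundary — an artifact
of three nearly collinear boundary nodes) are removed by flipping their
shared edge with the inner neighbour where that improves quality, or
dropped when no pinned node would be orphaned; finally a local
Laplacian pass moves free vertices of low-quality patches to their
neighbour average, each move accepted only if it strictly raises the
local minimum quality without flipping any triangle.  Connectivity is
frozen during this pass, so it can only improve the mesh.  Section
labels are then assigned by centroid → nearest-pixel lookup (ties at
half-pixel coordinates round toward negative row/col, stated so results
are reproducible; centroids on border pixels take the nearest
non-border label by EDT), and hole elements are excised with a node
renumbering map kept for traceability.

Non-convergence at `max_iter` is a warning with the partial mesh
returned and flagged — partial meshes are useful diagnostics — while a
domain too thin to hold any triangle is an error.

Quality is reported as the radius ratio `q = 2·r_in/r_circ`
(`(b+c−a)(c+a−b)(a+b−c)/(abc)` in side lengths): 1 for equilateral, 0
for degenerate.  On all built-in geometries at `h0 = 8` the generator
achieves `min q ≥ 0.5` and `median q ≥ 0.95`.

## Corrugation

The secondary image maps intensity to relief: black (0) is the maximum
height, white (1) the minimum, grey values intermediate extrema in
proportion to intensity — `z = A·(1 − v)` after bilinear interpolation
at each node.  A grey background simply yields a nonzero reference
plane, which subsumes both white-background and grey-background
conventions without special-casing.  The amplitude `A` defaults to 5%
of the larger frame dimension (wing-like proportions) and should be set
explicitly when physical units matter.

Smoothing is synchronous 3×3-mean relaxation with windows truncated at
the image edge (corners average 4 values, edges 6), which preserves the
discrete maximum principle without inventing a padding convention.
Unconstrained iteration is pure diffusion: it flattens every image
toward a constant, which would erase the encoded extrema long before
the published iteration ranges (tens to hundreds of passes) — so by
default the extremum pixels are re-imposed after every pass, turning
the iteration into relaxation toward a smooth interpolation of held
boundary values.  The literal unconstrained behaviour remains available
(`constrain=False`).  Extremum pixels are auto-detected as deviating
more than 0.05 from the modal background value; an explicit mask image
overrides the auto-detection.  The iteration count controls sharpness:
the maximum cross-extremum gradient decreases monotonically with it
(verified over 20…300 passes).

## Export

Sectioned meshes are written as an Abaqus-dialect deck: `*NODE`
(`id, x, y, z`, 6 decimals, z = 0 for planar models), `*ELEMENT,
TYPE=S3` (3-node shells — the standard triangular shell code for this
kind of thin-structure analysis), one `*ELSET`/`*SHELL SECTION`/
`*MATERIAL`+`*ELASTIC` trio per section.  When no materials are given a
placeholder linear-elastic set (E = 1, ν = 0.3, t = 0.01) is written so
every deck is complete and analyzable; these are deliberately not
biological values.  Output is byte-stable: identical inputs produce
identical files, and the whole pipeline is deterministic under a fixed
`rng_seed`.  A minimal reader parses node/element/elset blocks (and
skips unknown keywords) for roundtrip testing only.

## Synthetic test geometries

All test images are generated programmatically: rectangles, partitioned
rectangles, rectangles with circular discontinuities, Fourier-perturbed
irregular blobs, ridge heightmaps, random blob images for flood-fill
stress tests, and a wing-like pattern — a stadium (obround) silhouette
crossed by gently bowed longitudinal veins and short crossveins,
partitioning the interior into ten or so cells.  The stadium shape and
the compressed vein fan (±0.62 of the half-height, correlated bows) are
deliberate: they keep every vein–margin crossing steeper than ~50° and
every membrane strip wider than ~1.6·h0, the regime where a valid
`h0 = 8` mesh exists.  Real wings photographed at higher resolution
relative to `h0` pose no such constraint, but these fixtures do not
emulate photographic noise, vein taper, or anti-aliased edges — passing
tests demonstrate the pipeline's correctness on clean rasterizations,
not robustness to segmentation artifacts.

## Known limitations

* Meshing quality guarantees assume features (cells, gaps) no smaller
  than about 1.5·`h0`; thinner passages degrade quality or trigger the
  degenerate-domain error by design.
* The corrugation model is a height field: overhanging or folded
  geometry (z multivalued in the plane) cannot be represented.
* The `.inp` writer covers geometry, sections and elastic materials
  only — no steps, loads, or boundary conditions.
* Subdomain/hole seeds are trusted as given; there is no automatic
  seeding of enclosed cells.
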