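# wingforge

Finite-element shell models of insect wings (and other thin, bordered
structures) straight from a black-and-white image.

Insect wings are thin shells stiffened by a network of veins that
partitions the membrane into cells, often with out-of-plane corrugation.
Building FE models of such geometries by hand in CAD is slow and
error-prone, which pushes comparative biomechanics studies toward
oversimplified models.  `wingforge` automates the whole path: give it a
raster image in which black pixels are borders (the wing outline and
veins) and white pixels are membrane, click one seed pixel per cell, and
it produces an Abaqus-dialect `*.inp` shell model with one section per
cell, optionally corrugated out of plane from a second image.

## Method

The pipeline chains four ideas:

1. **Burning algorithm (region detection).**  A frontier-based flood
   fill expands from each user seed through 4-connected white pixels,
   collecting adjacent black pixels as that region's boundary, until no
   new white pixel is found.  Run from the frame edge it finds the
   exterior; run from each seed it finds each subdomain (cell) and each
   discontinuity (hole/crack).  The result is a total label partition
   of the image.

2. **Image-derived distance functions.**  The meshable domain (union of
   cells, internal walls, and discontinuities) is turned into a signed
   distance field `d(x, y)` — exact Euclidean distance transform at
   pixel centres, bilinear in between, negative inside — plus a sizing
   field `h(x, y)` (uniform, or graded `1 + g·|d|`).

3. **Force-equilibrium Delaunay meshing.**  Nodes seeded on an
   equilateral lattice of spacing `h0` relax under repulsive bar forces
   `F = max(L0 − L, 0)`; the triangulation is recomputed by Delaunay
   whenever nodes drift; nodes leaving the domain are projected back
   along `∇d`.  Pixels on subdomain interfaces and samples of the
   outline are pinned (`pfix`) so section boundaries are traced by
   element edges.  Discontinuities are meshed through, then their
   elements are excised.

4. **Corrugation.**  A second grayscale image encodes relief: black
   pixels mark maximum height, white minimum, grey intermediate
   extrema.  Synchronous 3×3-mean smoothing passes
   (`v ← mean of the 3×3 neighbourhood`, extremum pixels re-imposed
   each pass) relax the map; node heights are `z = A·(1 − v)`.  The
   iteration count controls how sharp the corrugations stay.

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

Mesh a built-in test image — a rectangle split into two cells with a
circular hole (radius 10 px) in the first cell:

```python
from wingforge import fixtures as fx
from wingforge.pipeline import RunConfig, run_pipeline

img, seeds = fx.make_holey_rectangle()           # 100x200 px image
cfg = RunConfig(
    subdomain_seeds=[tuple(s) for s in seeds.subdomain_seeds],
    hole_seeds=[tuple(s) for s in seeds.hole_seeds],
    output="model.inp",
)
result = run_pipeline(cfg, image=img)
for k, v in result.report.items():
    print(f"{k}: {v}")
```

prints

```
n_nodes: 295
n_elements: 507
n_subdomains: 2
n_holes: 1
elements_per_section: {1: 247, 2: 260}
removed_hole_elements: 12
quality_min: 0.7354418709164714
quality_median: 0.9820619290003114
converged: True
iterations: 178
corrugated: False
elapsed_s: 0.154
```

Two cells became sections of 247 and 260 triangles; the 12 elements
whose centroids fell inside the hole were excised after meshing; the
radius-ratio quality `q = 2 r_in / r_circ` (1 for equilateral) has
minimum 0.74 and median 0.98; the force equilibrium converged in 178
pseudo-time steps.  `model.inp` starts with the node block:

```
*HEADING
wingforge model
*NODE
1, 100.000000, 88.500000, 0.000000
2, 100.000000, 10.500000, 0.000000
3, 100.000000, 80.000000, 0.000000
```

The same flow is available from the shell:

```sh
wingforge fixtures make holey --out domain.png
wingforge run --image domain.png --subdomain-seed 11,55 --subdomain-seed 49,144 \
    --hole-seed 49,55 --h0 8 --output model.inp
```

Add `--height-image relief.png --iterations 100 --amplitude 10` to
corrugate the model out of plane.

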