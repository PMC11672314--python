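# Methods

This note documents the models, conventions and numerical choices behind
tesserakit, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Conventions

Volumes are indexed `[x, y, z]` with isotropic voxels; the world coordinate
of a voxel centre is `(index + 0.5) · voxel_size` µm. Label 0 is background
(including the unmineralized intertesseral gap); tile ids start at 1.
Foreground uses 26-connectivity and background 6-connectivity, the standard
complementary pair for 3-D binary topology. All lengths are µm, areas µm²,
volumes µm³, curvatures µm⁻¹ / µm⁻².

## Synthetic phantoms

The generator emulates µCT data of a thin mineralized shell subdivided into
tiles:

* **Growth centres** are a hard-core point process: uniform dart throwing
  with rejection below a minimum spacing (geodesic on the sphere, intrinsic
  on the cylinder). The hard-core radius stands in for the hypothesis that
  incipient tiles need a minimum cell-cluster size; beyond that the spatial
  statistics of real growth centres are unknown, and no further realism is
  attempted. Dart throwing fails loudly (reporting the achieved count) when
  a packing is infeasible.
* **Tessellations** are Voronoi diagrams. Planar diagrams are computed with
  seeds mirrored across each domain edge, which makes every real cell
  bounded and clipped *exactly* at the box (the bisector between a seed and
  its own mirror is the box edge); spherical diagrams use convex-hull
  duality (`scipy.spatial.SphericalVoronoi`); cylindrical diagrams unroll
  the surface with periodic copies across the seam and mirror copies across
  the rims. Closed trivalent pentagon/hexagon tilings (the fullerene-like
  family) are built as duals of subdivided icosahedra.
* **Voxelization** assigns each shell voxel to its nearest seed unless the
  distance difference between the two nearest seeds is below the gap width
  (exactly the band within gap/2 of the Voronoi bisector), carves spherical
  cell lacunae strictly inside tiles (with a two-voxel clearance so voids
  are genuinely enclosed, and a margin from the array faces), and renders
  grayscale as the blurred (Gaussian, σ in µm), noised (additive Gaussian)
  binary support of the labels at unit contrast.

**Default study conditions** (`pipeline.DEFAULT_PHANTOM`): a 1500 × 1500 µm
flat slab shell, 100 µm thick, voxelized at 5 µm, 400 growth centres with
≥ 50 µm spacing, 10 µm gaps, two lacunae of 7.5 µm radius per tile, blur
σ = 2.5 µm (half a voxel) and noise sd = 10 % of the contrast, seed 7. The
lacuna radius and blur are the generator's own choices (small voids of a
few voxels, sub-voxel scanner blur — typical of lab-µCT shells at this
resolution); the remaining values define the benchmark geometry. Slab
phantoms get 25 µm of unmineralized core below and 75 µm of air above, so
the outward direction is asymmetric but detectable.

What phantoms do **not** emulate: anatomical shape (curvature enters only
as plane/cylinder/sphere regimes), intra-tile mineral-density banding,
beam hardening or other scanner artifacts, and spatially correlated noise.
Passing the recovery benchmarks therefore shows the pipeline is correct and
well-calibrated on geometrically faithful data, not that it is robust to
every real-world artifact.

## Segmentation

Thresholding is explicit (a config value); an Otsu proposal is available
but never applied silently. Cleaning removes foreground components below a
voxel-count floor and fills background components that do not reach the
volume border and are at most `max_void_extent` voxels — the lacunae.

The instance stage is a hierarchical watershed on the Euclidean distance
transform. Persistence merging is implemented as the h-maxima transform:
grayscale reconstruction of `dist − h` under `dist`, whose regional maxima
are exactly the maxima with dynamic (peak minus saddle) ≥ h. Each
foreground component's global maximum always survives (infinite dynamic),
so persistence larger than every internal saddle yields one label per
component. Markers are labelled under the configured connectivity and grown
with `skimage.segmentation.watershed` on `−dist`, masked to the foreground;
ties follow the flood order of that implementation, which is deterministic
for fixed inputs. The default persistence should be of order half the
expected tile half-width (18.75 µm for the default phantom, whose tiles are
~75 µm wide); it is the knob separating "two maxima inside one tile" from
"two tiles bridged by noise".

The distance transform is 3-D. For thin shells it reduces to the in-plane
behaviour away from the faces, which is the regime the tile-separating
saddles live in; a surface-parameterized 2-D transform was deliberately not
implemented.

`remove_partial_tesserae` filters on volume and on thickness measured as
the *smallest* bounding-box side — for thin-shell tiles the outward axis is
the thinnest dimension, and this keeps the filter independent of the
signed-distance machinery.

## Region adjacency graph

Contact is face adjacency (6-connectivity) with a minimum contact-pair
count; diagonal-only contact is ignored as the conservative choice. Gap
bridging expands every label into the background by `bridge_gap / 2` using
the nearest-label Euclidean expansion and takes the face adjacency of the
expanded labels — two tiles become neighbours when their supports approach
within the bridge distance. A sensible default is the expected gap width
plus one voxel. Neighbour pairs whose shared Voronoi edge is much shorter
than the gap width can be pinched off by a third tile during expansion;
these are the residual false negatives in the benchmark (precision stays
at 1.0) and correspond to the contacts that required manual edge addition
in interactive workflows. Boundary tiles (within a configurable margin of
the volume faces) are flagged and excluded from polygon-class statistics,
since their degree undercounts their sides.

## Morphometry

* **Outward axis**: the signed distance field (negative inside mineral) is
  summed voxel-by-voxel along ±x, ±y, ±z from the tile centre; the maximum
  sum is outward. Rays run to the volume border by default — appropriate
  for tightly cropped scans. For shells enclosing a large hollow or
  unmineralized core, the core out-sums the outside air on inward rays, so
  `max_range` caps the ray length; a few shell thicknesses works well. Ties
  break deterministically (+z > +y > +x > −z > −y > −x).
* **Thickness / width**: axis-aligned bounding-box sides. Thickness is the
  side along the outward axis; width is the larger of the two remaining
  sides, so columnar tiles (taller than wide) are not misread. Axis-aligned
  boxes overestimate the thickness of strongly tilted tiles; this matches
  the cuboid-frame definition rather than an oriented-box refinement.
* **Plane-based area**: neighbours are ordered angularly about the tile
  centre in the fitted plane; the centroids of consecutive fan triangles
  (centre, nbrᵢ, nbrᵢ₊₁) are projected onto the plane through the centre
  perpendicular to the fitted normal, and the polygon's shoelace area is
  returned. The normal is the average of the fan-triangle normals (seeded
  by the smallest principal direction of the neighbour cloud); collinear
  degeneracies resolve by id order. On the regular hexagonal lattice with
  spacing s the construction is exact: the triangle centroids coincide with
  the Voronoi vertices and the area is (√3/2)s². On the square lattice the
  same rule gives (4/9)s² — the fan centroids sit at s/3, not at the edge
  midpoints.
* **Smoothed surface and curvature**: the RAG's 3-cliques triangulate the
  coarse tile-centre surface; the mesh is midpoint-subdivided once and
  smoothed with shrink-compensated (λ/μ = 0.5/−0.53) umbrella iterations —
  plain Laplacian smoothing shrinks a sphere of tile-centre scale by ~7 %,
  biasing curvatures high, while the compensated scheme keeps radii within
  ~3 %. Boundary vertices of open sheets are held fixed. Principal
  curvatures come from a local quadric fit (with linear terms absorbing
  normal error) over each vertex's 2-ring, signed so that a convex surface
  with outward normal has positive curvature; the default of 10 smoothing
  iterations recovers sphere curvature to within ~7 % (K) and ~5 % (H) on
  the 400-cell benchmark. A tile's (K, H) is read at the mesh vertex
  nearest its centre.

## Tessellation statistics

The Euler characteristic is computed from deduplicated vertices/edges and
is only defined here for closed tessellations; open surfaces are refused
rather than silently corrected, because boundary faces would need separate
accounting (real shells are almost, but not fully, covered — callers should
treat boundary cells explicitly). The hexagonal deficiency Σ(6 − n)
additionally requires trivalence (it equals 6χ only then) and reports the
offending vertex otherwise.

The "peak value" of a size distribution is the histogram mode under
Freedman–Diaconis binning, lightly smoothed (moving average, ±2 bins) and
refined with a parabola through the modal bin and its neighbours — the
smoothing cuts the estimator's sampling noise roughly in half at n = 10⁴
without biasing the n = 10⁵ benchmark beyond 3 %. A fixed bin rule can be
supplied for strict reproducibility. Rescaled distributions live on a
shared grid (x = value/mode ∈ [0, 4], 80 bins) with density normalized to
peak 1; the self-similarity distance renormalizes both densities to unit
area and takes their L1 distance (0 identical, 2 disjoint).

Peak–surface-area regressions are OLS on log₁₀ by default, with reduced
major axis as an explicit option (never silently applied). Isometric
reference slopes follow from dimensional analysis: 0.5 for lengths, 1 for
areas, 1.5 for volumes against surface area.

## Growth model

State: tile centres (scaled by the cumulative substrate factor λ_cum about
the origin), per-directed-neighbour front offsets f_ij, and per-fiber gaps
g_ij = λ_cum·d⁰_ij − f_ij − f_ji ≥ 0. Tiles are intersections of
half-planes at the front offsets, which makes apposition a scalar update
per face and makes overlap-freedom provable: no rule ever advances a front
past the gap midpoint. Boundary cells additionally carry "wall" half-planes
inherited from the clipped Voronoi cell; walls scale with the substrate,
and a wall front advances by the full rule increment since there is no
opposing front.

`init_state` shrinks every Voronoi cell toward its centre by
√fill_fraction (support distances scale linearly under central scaling, so
fronts start at √f·d/2 and coverage starts at the fill fraction).
Expansion is isometric, as the observed scaling justifies; the gap opened
on each fiber is exactly (λ − 1)·d_ij, so larger spacings open larger gaps
— the geometric seed of the whole argument.

The proportional rule is implemented as *gap*-proportional with equal
increments on both fiber ends (equal fiber force). Size-proportional total
accretion is then emergent, not imposed: larger tiles have larger gaps
opening beside them and accrete more per cycle. The Voronoi deviation of a
fiber is the offset of its gap midline (contact point once closed) from the
centre midline, |f_ij − f_ji| / (2 d_ij); expansion shrinks it and the
proportional rule preserves front asymmetry, so the mean deviation is
provably nonincreasing — the convergence-to-Voronoi property in its
simplest form.

New-tile insertion is detection only: uncovered connected regions above an
area threshold are reported with centroid and area, never inserted, since
constant tile number is the observed regime. A 1-D chain mode shares the
gap/apposition arithmetic and serves as the analytically checkable
reduction (all the closed-form examples in the tests use it).

Default simulation scale: 500 tiles on a 2000 × 2000 µm plane, 10 cycles of
λ = 1.07 (≈ 1.97× total linear growth, matching a roughly two-fold length
increase), fill fraction 0.9, constant-rule δ = the initial median
half-gap. These sizes keep a full two-scenario, ten-seed comparison within
a couple of minutes on one CPU while leaving hundreds of interior tiles
per run.

## Known limitations

* The watershed tie rule is the flood order of the underlying
  implementation, not an explicit lower-id preference; results are
  deterministic but not specified voxel-by-voxel at exact ties.
* Gap bridging cannot recover neighbour pairs whose shared boundary is much
  shorter than the gap width (pinched off by a third tile); such contacts
  need manual RAG edits, as in interactive practice.
* Bounding-box thickness/width are frame-aligned and biased for tilted
  tiles (by design, matching the cuboid definition).
* Out-of-plane (thickness) growth has no rule in the simulator; the model
  is strictly in-plane.
* Volume I/O is TIFF stacks; no NRRD writer is included.
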