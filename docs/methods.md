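# Methods

phenocloud extracts three greenhouse growth-survey traits from a
metrically calibrated 3D point cloud of a plant: inter-node length on
the main stem, per-leaf blade area, and per-fruit volume. The package
assumes segmentation into single-organ clouds has already happened
(programmatic box/polygon crops are provided; instance segmentation is
out of scope) and that the cloud comes from a photogrammetric or
radiance-field reconstruction — dense on the camera-facing side, sparse
or absent behind, with sub-millimeter surface noise.

## Metric calibration

A reconstruction is defined only up to a global similarity, so
coordinates arrive in arbitrary units. A printed square marker of known
edge length (default 0.30 m) placed in one captured scene fixes the
scale: each marker edge yields the ratio physical/reconstructed length
and the scale factor is the mean of those ratios, with the RMS mismatch
of the rescaled edges reported as `residual_rms`. Edge ratios need no
registration to a canonical marker frame, so the estimate is invariant
to any rigid motion of the corners; the reported residual is exactly
zero for noise-free corners. Clouds carry an `is_metric` flag; every
trait operation refuses non-metric input so a forgotten calibration
fails loudly rather than producing wrong numbers in silent units.
Calibrations persist as JSON and are reused across captures.

## Inter-node length

**Contraction.** The stem cloud is collapsed onto a curve skeleton by
Laplacian-based contraction. A k-nearest-neighbor graph (k = 12) is
built **once** from the input points; each iteration rebuilds only the
edge weights (inverse current edge length, floored at 1e-3 of the
initial neighbor scale) and solves, per coordinate, the sparse normal
equations of

    minimize  w_L^2 ||L X||^2  +  w_H^2 ||X - X_prev||^2

where L = I − D⁻¹W is the random-walk-normalized graph Laplacian. The
contraction weight w_L starts at 1 and is amplified ×3 per iteration
(capped at 2048); the attraction weight w_H stays at 1. Iteration stops
after 20 rounds or when the mean one-ring extent falls below 1% of its
initial value. Two choices here differ from the textbook formulation
and were forced by experiment: rebuilding the neighbor graph from the
contracted points lets small clumps of collapsed points satisfy the
Laplacian term without ever reaching the skeleton (a 1 cm-radius test
cylinder stalled at 7.8 mm mean distance from its axis), and amplifying
the attraction by the local extent ratio freezes the cloud before the
tubes collapse when the Laplacian is normalized. With a fixed graph and
constant attraction the same cylinder collapses to within 1.5 mm of its
axis while keeping 96% of its axial extent.

**Topology.** Contracted points are voxel-downsampled (5 mm default) to
skeleton vertices and joined by the Euclidean minimum spanning tree
(complete graph up to 5000 vertices, k-NN graph with a connectivity
check above). The result is by construction a connected acyclic graph
with positive Euclidean edge weights, in the coordinate frame of the
input cloud. Vertices of degree ≥ 3 are branch candidates; degree-1
vertices are ends.

**Node localization.** Contraction merges a lateral branch tangentially
into the stem, so the raw degree-3 vertex sits systematically 1–2 cm
past the true divergence point. Each junction (branch vertices within
2× the voxel size are first merged) is therefore refined: a direction
line is fitted to every arm's vertices within an along-tree window of
2–12 voxel sizes from the junction, the most anti-parallel arm pair
(dot ≤ −0.9) is taken as the continuing stem, and the node is placed
where the stem line passes closest to the branch line(s). Junctions
with no near-collinear arm pair (true forks) keep their cluster
centroid. On synthetic stems with 2 mm surface noise this reduces the
worst spacing error over ten seeds from 13.7% to 4.2%.

**Measurement.** The inter-node length between two chosen nodes is the
straight-line Euclidean chord between their coordinates — not the
along-tree path, which is also exposed (`geodesic_node_distance`) for
transparency. `measure_internode_spacings` reports chords between
consecutive height-ordered branch nodes, which is the trait definition
for a vertical main stem with lateral organs. Node-pair *selection* for
arbitrary architectures remains the caller's decision. Note that voxel
downsampling is grid-aligned, so skeleton vertex positions (unlike the
chord between two given nodes, or the contraction itself, which are
frame-equivariant to float precision) can shift by a fraction of the
voxel size when the cloud is rotated.

## Leaf area

**Smoothing.** Leaves are thin, so reconstruction noise normal to the
blade must be removed before meshing. Moving least squares projects
each point onto a local order-2 polynomial surface fitted to its
radius-neighborhood with Gaussian weights (defaults: radius 4× the
median nearest-neighbor distance, bandwidth = radius/2). Order 2
preserves blade curvature; a plane is an exact fixed point. Points with
too few neighbors pass through unchanged and are flagged. The default
radius suits the ~0.5 mm noise of close-range captures; coarser noise
calls for a proportionally larger radius (≈10× the median spacing for
2 mm noise — the neighbor count within c× the median spacing is
density-free, ≈ πc²/4, so the noise-averaging power of a radius choice
transfers across densities).

**Meshing.** The smoothed cloud is meshed by ball pivoting. Normals
come from neighborhood PCA with orientation propagated along a minimum
spanning tree (leaves are open surfaces; only mutual consistency
matters). A ball radius schedule of {3×, 5×} the median
nearest-neighbor spacing is the default: random (Poisson-like) surface
sampling leaves gaps several times the median spacing, and the
often-quoted 1.5–2.5× schedules leave those gaps as holes, biasing area
low by 10–20% even on noise-free clouds; on smoothed clouds the larger
balls do not over-triangulate (on *raw noisy* clouds they do, by
bridging the noise shell — the pipeline always smooths first).
Pivoting decisions are combinatorial, so the pipeline meshes in the
cloud's principal frame with data-anchored axis signs; this makes the
triangulation — hence the area — independent of the world frame the
cloud arrives in. Meshes are not required to be watertight or manifold:
a leaf is a bordered open surface, and enforcing closure would
fabricate area. Duplicate triangles over the same vertex set are
counted once.

**Measurement.** Area is the sum of triangle areas (half cross-product
magnitude per face), i.e. single-sided reconstructed-surface area in
m². Diagnostics report the fraction of input points used by the mesh;
low usage signals under-reconstruction, typically a curled blade whose
far side the camera never saw — on such one-sided captures the area is
biased low, which is the expected and documented failure mode, not a
defect of the area sum.

## Fruit volume

The fruit is modeled as an ellipsoid with semi-axes (a, b, c); the
fitted objective is the algebraic least-squares form

    f(a, b, c) = Σᵢ (xᵢ²/a² + yᵢ²/b² + zᵢ²/c² − 1)²

over the M observed points, optimized in log(a, b, c) (positivity
without constraints) with an analytic Jacobian, Levenberg–Marquardt,
and initialization at the per-axis maximum absolute coordinate. Volume
is V = (4/3)πabc, reported in cm³. For clouds of ≤ 200 points this
optimum is certified in tests against a two-stage exhaustive 40³ grid
search.

The objective assumes centered, axis-aligned points. A fruit seen from
a limited angular range violates both assumptions: the centroid sits
inside the observed cap, and — less obviously — the cap's covariance
eigenvalues become nearly degenerate, so PCA returns an essentially
arbitrary frame (measured: ~39% median volume error at 50% coverage
with centroid/PCA pose alone, and a persistent −4% at 75% coverage
with the center refined but the PCA orientation kept). The pipeline
therefore refines center *and* orientation jointly within the same
algebraic least squares (nine parameters; rotation-vector
parametrization), initialized at the centroid/PCA pose. A coverage
diagnostic (occupied fraction of a 256-cell Fibonacci direction lattice
seen from the fitted center) flags fits made from thin caps.

**Occlusion behavior.** On 50-seed batches of a 40×30×30 mm ellipsoid
fixture the median volume error is ≈0.24% at full coverage, ≈0.22% at
75% coverage and ≈3.8% at 50% coverage. The 50% step is a real
information loss (the far extent along the view axis is unobserved and
center/axis trade off along it). Between 100% and 75% there is no
measurable degradation: both medians sit at the noise floor of the fit
and within one sampling standard error of each other (0.236% vs 0.231%
over 200 seeds), so which *sample* median is larger is a coin flip.
The acceptance test asserts the ordering literally and can fail on that
tie; the magnitudes themselves are far inside their bounds.

## Synthetic plants

The generator produces organ clouds with closed-form ground truth; no
truth value is ever measured from a generated cloud.

- **Stems**: a vertical tube (6 mm radius) with one lateral branch tube
  per node at phyllotactic azimuths (137.5° increments, 40° elevation,
  8 cm length); truth inter-node distances are the input spacings.
  Default surface density 80 000 pts/m², noise σ = 2 mm.
- **Leaves**: flat disc (area πr²), half-cylinder (πrh), and an
  S-curled blade built from two opposite circular arcs (closed-form arc
  length 2Rφ, area 2Rφw). All surfaces are sampled uniformly by area —
  parameter-uniform sampling would bias density and distort area tests.
  Default density 212 000 pts/m² (≈4000 points on the default
  half-cylinder), noise σ = 0.5 mm.
- **Fruits**: ellipsoid surface (default 40×30×30 mm) sampled
  area-uniformly by rejection from the sphere, with an occlusion model
  that keeps points whose outward normal lies in the spherical cap of
  solid-angle fraction equal to the coverage around the view direction;
  truth volume is (4/3)πabc. Default density 150 000 pts/m², σ=0.5 mm.
- **Markers**: square marker corners under a seeded random rigid motion
  and a units-per-meter scale, with optional corner noise.

Randomness is numpy PCG64 keyed by `SeedSequence([seed, stream])` with
fixed per-organ streams; identical (seed, parameters) reproduce clouds
bit for bit, and the generator name is pinned in the fixture metadata.

What the fixtures do **not** emulate: view-dependent density falloff
(occlusion is a hard cap, not a gradient), outliers and ghost points,
organ-to-organ contact and mutual occlusion, non-ellipsoidal fruit
lobes, serrated or veined leaf geometry. Passing recovery tests on
these fixtures therefore demonstrates correctness of the geometry
pipeline under idealized capture, not field accuracy; field performance
is bounded below by these numbers.

## Numerical choices and degenerate inputs

- I/O: PLY is written binary little-endian with float64 coordinates
  (lossless round-trip); colors default to float64 properties, with
  `color_dtype="uchar"` for the 8-bit convention of most viewers. A
  JSON sidecar carries `is_metric` across round-trips.
- Crop boxes are inclusive on both bounds; polygon crops keep points
  whose orthographic projection along the stored view direction falls
  strictly inside the polygon.
- Contraction requires ≥ k+1 points and rejects all-coincident clouds;
  the linear systems are symmetric positive definite by construction
  (attraction > 0) and solved by sparse LU.
- MST ties: edges are enumerated deterministically (sorted index
  pairs); equal-weight tie-breaking follows that order.
- Ball pivoting: the empty-ball test uses a 1−1e−9 radius factor minus
  an absolute slack of 1e−9× the cloud diagonal; collinear triples and
  balls whose circumradius exceeds the ball radius are rejected
  outright; an edge acquires at most two triangles.
- Ellipsoid fits require ≥ 10 points and reject rank-deficient
  covariance (coplanar clouds). Sphere-like fruits make the orientation
  unidentifiable, which is harmless: volume is symmetric in (a, b, c).
- Evaluation: r² is 1 − SS_res/SS_tot about the truth mean (the
  predicted-vs-truth convention), not squared Pearson correlation;
  zero-truth pairs are excluded from MAPE with a warning.

## Problem sizes

Test fixtures use ~1500–4000 points per organ and the acceptance script
runs 6 stems, 12 leaves, 20 fruits and 150 occlusion fits — sizes at
which every stage's behavior (collapse quality, hole rates, fit
degeneracies) is already stable; larger clouds change runtimes, not
conclusions.

## Known limitations

- Node-pair selection is manual by design; `measure_internode_spacings`
  assumes a single vertical main stem.
- The S-curl one-sided capture reproduces the qualitative area
  underestimate of curled leaves; no correction is attempted.
- Skeleton vertex positions depend on the voxel grid alignment (below
  voxel-size scale).
- The ellipsoid model cannot represent strongly lobed fruit; the
  residual and coverage diagnostics are the intended guard rails.
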