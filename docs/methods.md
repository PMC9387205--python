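# Methods

`chromacloud` converts a set of entities — genes, samples, taxa, anything
with a numeric profile — into colors whose perceptual differences mirror
the distances between the profiles.  It does this in two stages: reduce
the data to a 3D point cloud, then place that cloud inside the displayable
part of CIELAB color space with a similarity transform, so that every
point becomes a displayable color and all pairwise distance *ratios* are
preserved exactly.

## Color model

CIELAB (L\*, a\*, b\*) is used because it is approximately perceptually
uniform: Euclidean distance between two Lab triples approximates how
different the colors look.  Conversions go sRGB ↔ linearized RGB ↔ CIE XYZ
↔ CIELAB under the D65 illuminant (2° observer, white point
Xn, Yn, Zn = 95.047, 100, 108.883), with the IEC 61966-2-1 piecewise sRGB
transfer function (linear slope 12.92 below 0.04045 / 0.0031308, exponent
2.4 above) rather than the γ = 2.2 approximation, so the transform is
exactly invertible.

Two numerical choices matter:

* The sRGB→XYZ matrix is solved at import time from the primary
  chromaticities and the D65 white point instead of being hard-coded.
  With the commonly quoted 7-digit matrix, the white point misses
  (100, 0, 0) by about 0.014 Lab units; with the solved matrix the neutral
  axis r = g = b maps to a\* = b\* = 0 to machine precision, which the
  gamut geometry relies on.
* Hex quantisation uses half-away-from-zero rounding of 255·channel, so
  output tables are bit-identical across platforms.

## Displayable gamut

The gamut is the image of the unit RGB cube under sRGB→CIELAB.  Membership
is decided analytically — a Lab point is displayable iff its inverse image
lands in [0, 1]³ (tolerance 1e−9 per channel) — rather than by testing
against a triangulated boundary; a sampled boundary mesh exists only for
visualization.  The analytic test is exact and has no resolution
artifacts.

The fit penalty needs a distance for points outside the gamut.  We use a
ray overshoot: bisection (48 steps) along the segment from a fixed
interior point (the image of mid-gray sRGB (0.5, 0.5, 0.5), Lab ≈
(53.39, 0, 0)) to the query point finds the boundary crossing, and the
overshoot is the Lab distance from the crossing to the query.  This is
cheap, deterministic and continuous.  It is *not* the nearest-boundary
distance — for penalty purposes only the "zero inside, grows with
protrusion" behavior matters.  The construction assumes the gamut is
star-shaped around the interior point; the test suite validates this
empirically on seeded points (the sRGB gamut in CIELAB is mildly
non-convex but star-shaped in practice).

## Fitting the cloud into the gamut

The fit searches over a 7-parameter similarity transform: translation
(3), rotation (Euler angles about the L\*, a\*, b\* axes applied in that
fixed order, R = R_b·R_a·R_L), and one uniform scale.  Uniform scaling is
essential: it changes all pairwise distances by a common factor, so the
color encoding preserves the structure of the input exactly.

Before fitting, the cloud is normalised to centroid 0 and maximum radius
1; both are recorded so the transform can later be reapplied to new points
given in the original frame.  Only the convex-hull vertices of the
normalised cloud enter the objective — a similarity transform maps hull to
hull, so bounding the hull bounds the cloud, and the cost per objective
evaluation becomes independent of the input size.

The objective, maximised by Nelder–Mead, is

    (wL·extL + wa·exta + wb·extb) / (wL + wa + wb)  −  λ · mean_v overshoot(v)

where ext_k is the max−min extent of the transformed hull along axis k,
the weights (default 1, 1, 1) let a user prioritise spreading along
particular axes, and the mean runs over hull vertices.

**Penalty weight.** λ multiplies the *mean* vertex overshoot so its
meaning does not depend on how many hull vertices a cloud happens to have.
The flip side is that the marginal cost of letting one vertex protrude is
only λ/H for a hull with H vertices, while growing the scale gains up to
about 2 size units per unit of scale for a unit-radius cloud.  A weight of
order 10 therefore lets the optimum push a sizeable fraction of vertices
far outside the gamut; containment requires λ ≳ 2H.  The default is
λ = 1000, which keeps every hull vertex inside (measured protrusion ≈ 0)
for hulls of up to several hundred vertices — more than 3D clouds produce
in practice — while costing only a few percent of achievable size.  Note
λ ≲ 2 makes the objective unbounded (size grows faster than the penalty)
and the scale diverges; the config validator does not forbid this, but the
monotone-penalty property test documents it.

**Multi-start.** The objective is non-convex in the rotation angles, so
the simplex search restarts from 25 initial rotations: start 0 is the
identity and the rest draw angles uniformly from [0, 2π)³ using a
generator seeded from the fit config (default seed 42).  Every start
begins at the gamut interior point with scale 40 (comfortably inside for a
unit-radius cloud).  All solutions are returned ranked, so alternative
color schemes can be offered; ties go to the lowest start index, making
output deterministic.  Convergence uses simplex tolerances 1e−6 on
parameters and objective with at most 2000 iterations per start, and an
initial simplex whose edges are sized per parameter block (10 Lab units
for translation and scale, 0.6 rad for angles) — the default
5 %-of-x0 simplex is far too small for angle coordinates starting near 0
and stalls the search in shallow basins.  After the multi-start loop the
incumbent best is polished by restarting the simplex from it (same edge
sizes, up to 10 rounds, stopping when a round gains less than the
objective tolerance): re-expanding the simplex around a stalled point lets
the search climb out of premature convergence, so fits of the same cloud
under different rigid motions land in the same basin (the acceptance
script measures this as the rigid-motion objective change).

Multi-start Nelder–Mead offers no global-optimality guarantee; across
seeds and rigid motions of the input the best objective typically varies
by ~1–2 %.  The encode step re-checks the *whole* cloud (not just the
hull): because the gamut is not perfectly convex, an interior point can
fall slightly outside even when every hull vertex is inside.  Such points
are clamped in RGB with a logged count by default (`clamp=False` turns
this into an error naming the offenders).  Reported Lab coordinates are
pre-clamp, so the table's Lab distances remain an exact multiple of input
distances; hex strings are post-clamp, so they are always displayable.

## Reduction tracks

* **High-dimensional** (entities × features): PCA to at most 50
  components, then UMAP to 3 dimensions (default 15 neighbors).
* **Single-cell counts** (genes × cells; the genes get colors): per-cell
  depth normalisation x′ = log(1 + x·sf/total) with sf = 10⁴ and the
  natural log (a `log_base` switch exists; the widely used "LogNormalize"
  convention is natural-log despite often being described as a log2
  transform), then a 50-component *uncentered* truncated SVD — the counts
  are deliberately not centered or scaled — and UMAP with 50 neighbors.
  Zero-total cells are dropped with a warning.  Graph clustering of the
  genes is not performed: cluster labels would not influence the colors,
  which depend only on the 3D coordinates.
* **Distance matrix**: UMAP directly on the matrix with
  `metric="precomputed"` (default 15 neighbors).  The matrix must be
  symmetric (1e−8), nonnegative, zero-diagonal; an averaging symmetrizer
  is provided but never applied silently.

All tracks pass a `random_state` to UMAP, which then runs single-threaded
and deterministically: identical input and seed give identical
coordinates, and downstream identical color tables, byte for byte.

## Synthetic data

The generators in `chromacloud.synthetic` build datasets with a planted
3-group structure and return the group labels, so the pipeline's central
claim — similar profiles receive similar colors — can be tested without
external data:

* `clusters3d` / `highdim_clusters`: isotropic Gaussian clusters (σ = 1)
  with centers at mutual distance 10σ, in 3 or 50 dimensions.
* `sc_counts`: Poisson counts where the genes of a module share a
  cell-loading pattern (module mean 3.0 in the module's cells, background
  0.05 elsewhere; ~65 % zeros at the defaults).
* `cliques_dist`: three cliques with within-distance 0.1 and
  between-distance 10, plus 0.1 % tie-breaking jitter.

These emulate the *separation structure* of real data, not its messiness:
no batch effects, library-size gradients, dropout beyond Poisson zeros,
or overlapping clusters.  Passing tests therefore demonstrate that the
pipeline preserves genuine structure through reduction and color encoding;
they do not certify behavior on weakly structured or confounded data,
where UMAP's distortions dominate.

## Degenerate inputs and tie-breaks

Single-point clouds fit trivially (objective 0, the point is placed at the
gamut interior).  Clouds with ≤ 4 distinct coordinates, or collinear /
coplanar clouds, use all distinct points in place of hull vertices.
Distinct entities may share coordinates; they then receive identical
colors.  Equal objectives across starts resolve to the lowest start index.
A zero-radius cloud normalises with radius 1 instead of dividing by zero.

## Problem sizes

The packaged tests and the acceptance script run fits at 20–500 points
(hulls of ~10–40 vertices) with the full 25 starts, and reductions at
45–300 entities; these sizes exercise every code path while keeping a full
run in the minutes range on one CPU.  The fit cost scales with hull size,
not cloud size, so much larger inputs mainly pay for the reduction step.

## Known limitations

* No global-optimality guarantee; alternative ranked solutions partially
  compensate.
* The axis-weight convention (weights applied to the size term) is one of
  several defensible readings; weights could equally pre-scale coordinates
  or weight the penalty.
* Only the sRGB gamut is modelled (no P3/Rec.2020), and only hex output is
  quantised — downstream 8-bit rendering is assumed.
* UMAP coordinates, and hence colors, are not comparable across different
  UMAP versions.
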