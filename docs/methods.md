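# Methods

## Coordinate and unit conventions

Coordinates are image-style: `x` is the column index (rightward), `y` the row
index (downward), origin at the top-left pixel, 0-based. Annotation tools
export sub-pixel coordinates, and all distance computations use the raw
floating-point values; rounding to the pixel grid happens only for ROI-mask
membership (nearest pixel center) and area counting (1 px² per true mask
pixel). Any nonzero mask pixel is "inside" — masks are treated as hand-painted
binary images with no partial membership.

All internal calculations are in pixels. A single calibration, `nm_per_pixel`,
converts lengths (linearly) and areas (by the square) at output time only, so
changing the output unit never changes the analysis. The documented example
calibration is 30 nm = 27 px (≈ 1.111 nm/px).

## Nearest-neighbor distances

Particle↔particle NND and particle→landmark NND are exhaustive Euclidean
minima. The search is a vectorised all-pairs computation: ROIs carry at most
thousands of particles, where O(n²) is fast and has no approximation error; a
spatial index would have to reproduce it exactly to be admissible. Ties break
toward the lowest id, making outputs deterministic. Duplicate coordinates are
legal and produce NND 0 — deduplication is left to the user, since duplicates
can be real annotation artifacts worth seeing.

Distances are straight-line, not geodesic within the mask: on strongly curved
dendrites the particle→landmark distance understates the within-membrane
distance. Neighbor segments may also cross outside the ROI border; no
exclusion or border correction is applied.

The suite checks the classical Clark–Evans expectation — mean NND of a
homogeneous point process approaches $0.5/\sqrt{\lambda}$ — as an external
sanity anchor for the NND implementation.

## Random reference generation

The null model for every workflow is a uniform "dart throwing" process:
integer pixel coordinates drawn uniformly over the mask bounding box,
rejected if outside the mask or closer than `min_separation` (default 5 px)
to an already-placed random point. The separation constraint mimics physical
non-overlap of gold particles and applies **among the random points only** —
the reference must be independent of the real configuration, and random
points may coincide with real particle positions. Generation is seeded and
reproducible; `max_attempts` (default 10,000) consecutive rejections for one
point raise a saturation error reporting how many points were placed, which
signals that the requested count cannot be packed into the mask at the
requested spacing.

## Cluster analysis

Clustering is single-linkage at a distance threshold: particles are vertices,
edges connect pairs at center-to-center distance ≤ threshold, clusters are the
connected components. This is exactly the "overlapping circles" picture —
disks of the threshold radius drawn on each particle, groups formed by chains
of overlap — and is the only linkage for which the verbal and algorithmic
descriptions of threshold clustering coincide. The default threshold is 27 px
(30 nm at the example calibration), absorbing the labeling uncertainty of a
primary+secondary antibody bridge. The threshold is interpreted as the
maximum center-to-center linking distance; users who intend "circle radius
30 nm, link on overlap" should double it. Singletons are reported as clusters
of size 1; the separation analysis filters them out by default.

Cluster ids are assigned in order of each cluster's lowest particle id, so
partitions are reproducible run to run.

**Union-of-circles area.** The area of a cluster is the area of the union of
member-centered disks (radius defaulting to the threshold). A single disk is
returned analytically (πr²). For k ≥ 2 the union is rasterized on a 0.25-px
subgrid over the cluster bounding box, counting cell centers inside any disk.
At radius ≈ 27 px this is accurate to well under the declared 0.5% relative
tolerance (the suite cross-validates against the 2-disk lens closed form,
10⁶-sample Monte-Carlo integration, and polygonal buffering). Exact analytic
k-disk union was judged not worth its edge-case complexity at a 0.5%
tolerance. Areas are **not** clipped to the ROI: a cluster hugging the
membrane edge counts disk area outside the mask, which slightly deflates its
density. Density is size/area, in particles/px² (converted at output).

## Cluster separation

Centroids are arithmetic means of member coordinates. Clusters with at least
`min_cluster_size` particles (default 2) enter a centroid-to-centroid NND,
reported with cluster ids. Fewer than two qualifying clusters is reported as
a workflow-level error without aborting other workflows. When the random
reference is compared, random particles are re-clustered with the same
configuration first, so the comparison covers the full pipeline. No edge
correction is applied at ROI borders.

## Gold Rippler and the LCPI

Ripples are cumulative: ripple k is the set of ROI pixels whose centers lie
within radius $r_k = r_0 + k\Delta$ of **any** landmark (union over
landmarks — a pixel in two disks counts once), with defaults $r_0 = 50$ px,
$\Delta = 60$ px, 10 steps. The LCPI at $r_k$ divides the fraction of all
particles within $r_k$ of a landmark by the fraction of ROI area the ripple
covers.

Two normalization choices matter:

- The area denominator uses the **mask-intersected** ripple, not the raw disk
  area. This is the only reading under which uniformly distributed particles
  give LCPI = 1 on irregular masks, which is the index's defining no-bias
  property.
- Ripple area is counted on the mask grid itself (pixel-center rule, no
  supersampling), because the mask is the unit of ROI area; rasterized disk
  area converges to πr² within 1% for radii ≥ 20 px, which the suite checks.

When a ripple's area stops growing because it already covers the whole ROI
(saturation), both fractions are 1 and the LCPI is reported as exactly 1,
with the bin flagged as saturated. A ripple that covers no ROI pixel (landmark
far outside the mask with a small radius) has an undefined LCPI; the bin is
reported as missing (NaN) and the run continues. The random-reference run
re-uses the same mask and landmarks, randomizing only the particles.

## Simulation models

Five forward models of particle placement around a single landmark validate
the LCPI's behavior, each in a 400×400-px square arena treated as its own
full ROI with the landmark at the exact center, averaged over 100 iterations:

| model | n | placement |
|---|---|---|
| light_uniform | 55 | uniform over the arena |
| heavy_uniform | 220 | uniform over the arena |
| normal | 110 | isotropic Gaussian, σ = 60 px, truncated to the arena |
| u_shaped | 110 | uniform outside a 100-px central exclusion disk |
| ring | 110 | radius ~ N(100 px, 15 px), angle uniform, truncated |

The two uniform counts probe density resistance: sparse and dense labeling
must give the same flat LCPI ≈ 1 curve. The Gaussian σ, exclusion radius, and
ring parameters are package defaults chosen so the four qualitative curve
signatures (flat; high-decaying; rising-from-below-one; overshoot-and-return)
are each realized well inside the arena; all are configurable. The U-shaped
count matches the other biased models at 110.

Simulation binning defaults to initial radius 25 px, step 25 px, 8 steps
(radii 25–200 px): the analysis tool's on-image defaults (50 + k·60 px, 10
steps) would extend far beyond a 400-px arena, leaving most bins saturated
and uninformative. Truncation to the arena is by resampling, so every
iteration carries exactly n particles.

Averaged curves carry per-bin S.E.M. over iterations (NaN bins excluded), and
the suite verifies the S.E.M. shrinks roughly as 1/√iterations. Curve
classification is nearest-model by least-squares distance between LCPI
curves sharing the same binning; it is a forward-simulation lookup, not a
parametric fit.

A statistical caveat: in the first bin the ripple covers only ~1% of the
arena, so the per-iteration LCPI there is dominated by Poisson counting noise
(S.E.M. ≈ 0.06–0.14 after 100 iterations for the uniform models). Flatness
claims about the first bins are therefore claims about the mean over many
iterations, not about single realisations.

## Synthetic fixtures — what they emulate and what they do not

The fixtures module fabricates complete input folders: masks (rectangle,
ellipse, or a sinuous dendrite-like corridor with circular spine stubs, for
exercising irregular geometry), particle layouts (uniform; planted clusters —
tight groups of known membership around centers spaced far enough apart that
threshold clustering must recover the planted partition exactly; Gaussian
landmark-biased), landmarks, and a ground-truth JSON sidecar. The bundled
"image" is the mask rendered as grayscale — a synthetic stand-in, since only
the mask and coordinates enter any computation.

These fixtures emulate the geometry and point statistics of replica data, not
its imaging physics: there is no EM texture, no annotation error, no
double-labeling crosstalk, and no dependence of labeling efficiency on
membrane topology. Passing tests therefore demonstrate correctness of the
spatial computations and recoverability of planted structure, not robustness
to upstream annotation quality.

## Numerical choices

- Union-of-circles rasterization at 0.25 px; declared area tolerance 0.5%.
- NND ties break to the lowest id; cluster ids ordered by lowest member id.
- LCPI saturated bins → exactly 1; zero-area bins → NaN, run continues.
- Random generation uses a Mersenne-Twister-backed generator with an explicit
  seed recorded in the run manifest; simulation seeds are spawned from a
  single seed via a seed sequence (kept below 2³¹).
- Degenerate inputs raise typed errors (all-false mask, < 2 points for NND,
  empty landmark set, < 2 qualifying clusters, unpackable random request)
  rather than returning sentinel values; the pipeline logs the failed
  workflow and continues with the rest.

## Problem sizes used in the test suite

Oracle-equivalence checks run 100 random instances of up to 300 particles
against pure-Python brute-force and BFS references; Monte-Carlo area checks
use 10⁶ samples; uniformity checks span 200 seeds; simulation checks average
25–100 iterations. These sizes keep the whole suite under a minute on one
core while leaving each statistical assertion several standard errors of
headroom.

## Known limitations

- Euclidean, not geodesic, distances throughout (see above).
- Cluster areas are not clipped to the ROI mask.
- No border-corrected spatial statistics (Ripley's K, pair correlation).
- No 3-D support; 6-nm and 12-nm gold populations must arrive as separate
  CSVs.
- Batch execution over folders is possible by scripting the CLI, but no
  cross-image statistics are computed.
- The GUI of the original interactive workflow is replaced by the CLI and
  config files; downstream inferential statistics (paired tests, FDR
  correction across bins) are left to dedicated statistics environments.
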