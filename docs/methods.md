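# Methods

This note documents the models and procedures implemented in `vasctda`, the
defaults they run with, the numerical choices behind them, and what the
synthetic phantoms do and do not establish about real imaging data.

## From classified volumes to point clouds

Input volumes are per-voxel probabilities exported by a pixel classifier
(HDF5) or raw light-sheet stacks (TIFF), stored `(z, y, x)` with one TIFF
page per z-plane. A hard threshold (default 0.5, set per channel; the
upstream practice is to choose it by eye against the raw signal) turns the
volume into a point set: one point per super-threshold voxel at the voxel
centre, `(index + 0.5) × spacing`, in physical μm. Anisotropic spacing (e.g.
6.45 μm in-plane, 10 μm z-steps) is carried everywhere. Signal "volume" is
voxel count × voxel volume. Atlas region labels arrive as an aligned integer
volume; each point inherits the label of the voxel it falls in
(`floor(coord/spacing)`), with 0 meaning unlabeled.

We treat thresholding as hard binarization; probability weighting is not
carried downstream.

## Vietoris–Rips persistent homology

The filtration parameter is the **ball radius** r: a simplex is present once
all pairwise distances are ≤ 2r, so births and deaths are half the simplex
diameters. Engines that report distance thresholds (diameters) need their
outputs halved to compare; ours are already on the radius scale, in μm.

The engine computes H0 from the minimum spanning tree of the distance matrix
(equivalent to single linkage; edge weights are shifted by +1 before the
sparse MST so duplicate points are not dropped, then shifted back). H1 and
H2 use the dual (persistent cohomology) column reduction over Z/2: for each
dimension, coboundary columns are processed in decreasing filtration order
(ties broken lexicographically on vertex tuples); a column's pivot is its
earliest cofacet, and almost all columns claim their pivot without
arithmetic. Columns paired one dimension below are cleared, and edges that
merge components (dim-0 deaths) are skipped via union–find. Cofacets are
enumerated on the fly from the distance matrix, so 3-simplices are never
materialised globally. The diagram drops zero-persistence pairs (death =
birth), which Rips filtrations produce in abundance and which carry no
information. Features alive at `max_radius` are recorded with
`death = max_radius` and a `capped` flag, and are excluded from diagram
comparisons by default.

Defaults: `max_dim = 2` (loops and voids are the readouts of interest;
dim 0 is computed but excluded from comparisons unless requested),
`max_radius` = half the bounding-box diagonal (closes all finite features).

Correctness is established against an independent oracle that never touches
the reduction code: persistent Betti numbers β(i, j) computed from Z/2 ranks
and nullspaces of full boundary matrices, converted to pair multiplicities
by inclusion–exclusion. The test suite checks exact diagram equality on
closed-form configurations (square, regular 12-gon, scaled rings) and on
dozens of random clouds, with and without a restrictive radius cutoff.

**Scaling.** Cost grows steeply with N: the dim-2 pass touches all triangles
(C(N,3)) and their cofacets. Bifurcating-tree clouds at N = 120 take ~2 s;
sphere shells (the worst case for column fill-in, being pure 2-sphere
topology) take ~0.4 s at N = 50 and ~30 s at N = 100. The package therefore
subsamples clouds (uniformly, seeded) before Rips; the pipeline default cap
is 120 points when `max_dim = 2`. Whole-organ clouds should be analysed per
region and subsampled; the cap and seed are recorded in the run manifest.

## Sliced Wasserstein distance, kernel, and MDS

Diagrams are compared per homology dimension with the Sliced Wasserstein
distance: project both diagrams onto lines through the origin at angles
θ ∈ (−π/2, π/2], augment each side with the diagonal projection of the other
(equalising masses), take the 1-Wasserstein distance on the line (a sorted
sum of absolute differences), and average over angles. The integral is
discretised with M midpoint angles; M = 50 by default (the closed-form case
{(0,1)} vs ∅ = √2/π is reproduced to 10⁻³ with M = 10⁴, and convergence in M
is monotone in the tests). The similarity kernel is
`k_SW = exp(−SW/(2σ²))` with σ = 1 μm by default — note the exponent uses SW
itself, not SW²; this follows the defining formula we implement, and the
choice is configurable ground we deliberately do not revisit per analysis.

Multi-diagram comparisons sum the per-dimension SW distances over the
configured dimensions (default {1, 2}: loops and voids). The distance matrix
— not a kernel-derived transform — feeds classical (Torgerson) MDS:
double-centre the squared distances, take the top eigenpairs, scale by √λ
(clipped at zero). A fixed sign convention makes repeated embeddings
bit-identical; the eigenvalue spectrum is reported so non-Euclidean inputs
are visible. On planar configurations the embedding reproduces the input
distances with strain < 10⁻⁸.

## The NHPP intensity model

Vessel voxels are modelled as points of a non-homogeneous Poisson process
whose intensity is a sum of separable logistic kernels centred at the
observed points:

    g(u) = Π_i  a·b_i / (e^{b_i u_i} + 2 + e^{−b_i u_i}),   i = x, y, z
    λ(u) = Σ_{j : x_j ≠ u} g(u − x_j)

Each 1D factor is `a` times a logistic density with scale 1/b_i, so the
kernel's total mass is a³. `b_i` (1/μm) is the concentration along axis i:
vessels running *along* an axis spread mass out on it, giving a small b and
a large directionality readout 1/b_i. Evaluation uses the algebraically
equivalent `(b/4)·sech²(bu/2)` form via `exp(−|x|)`, stable for arbitrarily
large offsets. Leave-one-out at data points is by index, so duplicate
coordinates are handled.

The log-likelihood over an observation window (a 3D box — the only reading
that makes the likelihood well-defined in 3D) is

    log L = Σ_j log λ(x_j) − ∫_box λ(u) du,

with the box integral in closed form through the logistic CDF per axis and
per kernel centre; it matches adaptive quadrature to 10⁻⁶ and approaches
N·a³ as the box grows.

**Fitting.** All four parameters are positive, so the search runs in log
space. The strength has an exact profile: for fixed b,
`â³ = N / Σ_j coverage_j(b)` where coverage is the unit-mass box integral.
The remaining 3-parameter concentration search uses seeded multi-start
Nelder–Mead (5 starts; first start from a nearest-neighbour moment heuristic,
b ≈ π√(2/3)/sd of NN offsets) on a 500-point subsample, then polishes the
best start on the full data. Pairwise offsets are precomputed once per fit
(condensed upper triangle, float32); pairs guaranteed negligible for every
plausible b (`b_ref·|Δ| > 60` on any axis, an order of magnitude of slack)
are pruned up front. Non-convergence flags the result rather than raising.
The reported log-likelihood is recomputed exactly at the optimum, and the
fitted optimum is never worse than the generating parameters on simulated
data.

**What the strength parameter can and cannot measure.** The profile identity
`â³·Σ_j coverage_j = N` pins â at ≈ 1/⟨coverage⟩^{1/3} ≈ 1 for *any* point
pattern mostly inside its window: with kernels centred at the observed
points themselves, the maximum-likelihood strength only measures edge
leakage, not point density. This is a structural property of the printed
model, verified numerically, and it is why the verbal reading of a as "the
overall intensity" does not survive maximum likelihood. The model-consistent
overall-intensity readout is instead the fitted mean intensity over the
window, λ̄ = a³·Σ_j coverage_j(b̂)/V (the fitted model's expected count per
μm³). `fit` reports it as `mean_intensity`, and the block-comparison
procedure accepts `"intensity"` as the strength parameter — the recommended
choice; `"a"` and `"mass"` (= a³) remain available for the literal readouts.

Relatedly, simulation-based recovery of the concentrations carries an
intrinsic bias: the sampler draws offspring around latent centres with
logistic offsets of scale 1/b, so *pairwise* displacements between observed
siblings are logistic-differences — √2 wider than the kernel — and the MLE,
which fits the conditional intensity of each point given the others,
converges to a kernel wider than the generating one (b̂/b ≈ 0.8 at the study
conditions, median relative error ≈ 17–19%). The *ordering* of the axes is
preserved robustly (anisotropy recovery: 19–20 of 20 seeded replicates), and
that ordering — not the absolute scale — is what the directionality
comparison consumes. The recovery study (a = 1.5, b = (0.05, 0.05, 0.2)/μm,
≈ 590 centres in a 1 mm³ box, N ≈ 1900, 20 seeds) is rerun from scratch by
`scripts/acceptance.py` and its medians reported, not asserted away.

**Simulation.** `simulate` realises the matching cluster process: centres
uniform in the box, Poisson(a³) offspring per centre, per-axis logistic
offsets by inverse CDF, out-of-box offspring discarded with the retention
fraction reported. Deterministic per seed.

**Block comparison and Fisher procedure.** The window is tiled into cubic
blocks (default edge 500 μm; the spatial unit of "a part of the organ" is a
package choice). Blocks with ≥ 50 points in each channel are fitted
independently per channel; a block's region is the majority atlas label of
its points. For a chosen parameter (intensity, a, mass, or 1/b_i) a block is
"changed" when the channel-A/channel-B ratio is ≥ the fold threshold
(default 2; one-sided increase by default, |log₂ ratio| ≥ 1 optionally).
Each region then gets a 2×2 table — changed/unchanged × in-region/elsewhere
— and a two-sided Fisher's exact test (scipy's implementation; the test
suite checks it against full hypergeometric enumeration for every table with
total ≤ 20). If changed blocks scatter randomly, every region's ratio
matches the global one and p stays high; concentration of change in a region
drives its p down. Raw per-region p-values are reported (no correction by
default, matching per-area readouts at p < 0.05); a Benjamini–Hochberg
column is available as an option and recorded in the manifest.

## Tumour–vessel proximity

Distances between two structures (e.g. tumour voxels and lymphatic-vessel
voxels) are per-point nearest-neighbour Euclidean distances in μm via a
k-d tree, source → target (the relation is asymmetric and the direction is
the user's choice). Summaries are Tukey five-number statistics: quartiles by
linear interpolation of order statistics (conventions differ; this one is
fixed and documented), whiskers to the most extreme values within 1.5·IQR of
the hinges, outliers beyond. No aggregation of tumour voxels into colonies
is performed; distances are per point.

## Synthetic phantoms

The phantom generators provide seeded point clouds with known ground truth:

- **tube**: Poisson(density·length) points in a cylinder, ordered along the
  axis — a vessel segment;
- **ring**: points on a circle (equally spaced or Poisson), the ground-truth
  loop; with zero jitter the Rips diagram is the scaled circle closed form;
- **shell**: uniform points on a sphere, the ground-truth void;
- **tree**: recursive bifurcating tubes, 2^(depth+1) − 1 segments with
  geometrically decaying lengths and alternating bend planes — a branching
  vasculature surrogate;
- **uniform**: homogeneous clutter for null comparisons.

`degrade_phantom` deletes contiguous runs of points (geometric run lengths,
mean `clump_scale`) along the generation order, which for tubes and trees
cuts out spatial stretches — emulating fragmented, damaged vessels rather
than diffuse thinning. `rasterize` writes any cloud back to a voxel grid for
round-trip testing against the thresholding path.

**Discrimination study.** Six intact versus six degraded trees (40% removed
in clumps), subsampled to 120 points, diagrams compared with SW and embedded
with MDS. Because clump deletion preserves local density where points
remain, its signature is *connectivity*: components that merge only across
gap-sized distances. The study therefore compares dimensions {0, 1}
(fragmentation and loops) rather than the pipeline's {1, 2} default — a
choice made on that mechanistic ground. Between-group mean SW distance
exceeds the within-group mean (ratio ≈ 1.7 at the default conditions) and
the two groups are linearly separable in the 2D MDS plane.

**What phantoms do not show.** Phantoms have sharp boundaries, uniform
density, no imaging noise, no autofluorescence, no classifier errors, and
their "damage" is exact deletion. Passing these tests validates the
mathematics and the pipeline plumbing; it does not validate classifier
quality, threshold choice, or registration accuracy on real volumes.

## Problem sizes and tolerances used in the shipped studies

- Rips oracle equivalence: exact equality, clouds of N ≤ 8 (plus the 12-gon).
- SW: 50 slices in pipelines; 10⁴ slices against closed forms (tol 10⁻³);
  metric axioms at fixed slices to 10⁻⁹.
- NHPP closed-form integrals vs quadrature: 10⁻⁶ relative.
- Recovery study: 20 seeds at N ≈ 1900; phantom study: 12 trees at N = 120.
- Fisher vs enumeration: all 10 626 tables with total ≤ 20, exact.

## Known limitations

- The Rips engine targets subsampled clouds (≤ a few hundred points for
  dim 1, ≈ 120 for dim 2); it is exact but not a substitute for optimized
  C++ engines at larger N.
- The strength parameter of the NHPP is structurally uninformative about
  density (see above); use the `intensity` readout for strength comparisons.
- Concentration estimates carry the √2 pair-displacement bias on clustered
  data; cross-channel and cross-region *comparisons* (ratios, orderings) are
  unaffected to first order because the bias is shared.
- Subsampling before Rips discards density information by design; volume
  and intensity readouts come from the un-subsampled clouds.
- Block fits near window faces absorb edge leakage into â; blocks are
  compared to the matching block of the other channel, which cancels the
  effect in ratios.
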