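# Methods

This note documents the models and procedures implemented in
`neuromotif`, the choices made where the design was genuinely open, and
what the synthetic benchmark does and does not establish about real
reconstruction archives.

## Data model and coordinate conventions

A morphology is a pair of arrays: a *point* array of 3-D coordinates
and a *line* array of per-point records (structure label, point index,
parent index; −1 marks the root).  The parent relation must form a
tree rooted at a single record, every parent must precede its child,
and at least one point must be soma-labeled.  SWC structure codes map
1→soma, 2→axon, 3/4→dendrite; any other code is treated as dendrite
with a warning, since the analysis only distinguishes those three
classes.  Radii are read and preserved but unused.

All internal coordinates are micrometers in PIR orientation
(anterior→posterior, superior→inferior, left→right, origin at the
anterior-superior-left corner of the CCF template).  Storing
micrometers rather than voxel indices removes any ambiguity about
rescaling direction between 1 μm, 10 μm and 25 μm sources; voxel
indices are derived on demand by dividing by the atlas voxel size and
flooring (0-based, half-open voxel ownership).  MouseLight-style LIP
sources are normalized by swapping the first and third coordinates and
reflecting the resulting left-right coordinate as `extent_LR − value`,
with the template extent defaulting to 11,400 μm (configurable via
`SpaceSpec`).  The transformation is an isometry and is idempotent on
already-normalized data.

## Topological minor

The minor keeps the soma, the axonal branch nodes (points with ≥ 2
axonal children; trifurcations count once) and the terminal branches —
each recovered by backtracking from a childless axonal point through
its ancestors until a branch node or the soma is reached.  Interior
sample points survive only inside the stored branch paths, so branch
path lengths are preserved exactly while the working point cloud
(soma + branch nodes + terminal points) is typically several-fold to
an order of magnitude smaller than the raw reconstruction.  Terminal
points that duplicate their predecessor (zero-length final segments)
are deduplicated.

Morphometrics computed on the minor:

| measure | definition |
|---|---|
| `n_branch_points` | number of axonal branch nodes |
| `mean_radial_distance` | mean Euclidean soma→terminal-point distance (terminal points only; the radial arrow is conventionally drawn soma→terminal) |
| `mean_branch_width` | per branch node, the maximum pairwise distance among the terminal points descending from it, averaged over branch nodes |
| `total_terminal_length` | summed terminal-branch path lengths |
| `n_terminals` | number of terminal branches |

The width definition is rotation-invariant by construction (a
horizontal-extent bar over the arbor, measured intrinsically), so all
morphometrics are invariant under rigid motion of the whole cell.

## Projection statistics

The projection of a neuron to an area is the total path length (μm) of
the terminal branches whose *endpoints* lie in that area; the whole
branch length accrues to the endpoint's area and layer.  (Per-segment
length splitting would attribute passing fibers to areas they merely
traverse; endpoint assignment matches the notion of termination.)
Branches ending outside the configured areas tally under `other`.

* **Dominant target**: argmax of per-area length; ties broken by the
  canonical area order (SSp-bfd, SSp-n, SSp-m, SSp-ul, SSp-ll, SSs)
  and flagged.
* **Motif**: areas with ≥ 5 terminal branches, in descending terminal
  count.  |motif| of 0/1/2/3/4/≥5 maps to subthreshold / monofocal /
  bifurcating / trifurcating / quadrifurcating / higher; the census
  does not cap motif order.
* **Focality**: evaluated for the second-ranked motif area only.  A
  multifocal neuron is *center* if ≥ 4 of its secondary-area terminal
  points lie > 200 μm (3-D Euclidean, via a per-area distance
  transform cached on the atlas) from the nearest voxel of the
  dominant area, else *border*.  Whether border proximity should be
  measured in 3-D or along the flattened cortical sheet is an open
  question; 3-D is the simpler reading and is what the toy atlas can
  support.
* **Significance**: for each multi-area motif the null joint
  probability is the product of marginal per-area targeting
  probabilities (fraction of neurons whose motif contains the area);
  the observed count is tested with a two-sided exact binomial test
  against Binomial(n, Π p_area) and Bonferroni-corrected over the
  number of motifs tested.  The null ignores the single-dominant-target
  constraint, so it is conservative for motifs sharing a dominant area.
* **Barrel-level census**: the same machinery run against barrel
  labels, with a threshold of 4 terminal branches, partitioning
  barrel-targeting neurons into monofocal/multifocal × single-/multi-
  barrel.

## Rotation-only rigid CPD

Given a moving cloud Y (M×3) and reference cloud X (N×3), both
soma-centered, the moving points are treated as centroids of an
isotropic Gaussian mixture fit to X by EM over a rotation R about the
origin and the shared variance σ².  Per iteration:

* E-step: responsibilities
  `P[m,n] = exp(−|x_n − R y_m|²/2σ²) / (Σ_k exp(−|x_n − R y_k|²/2σ²) + c)`
  with the uniform-outlier constant
  `c = (2πσ²)^{3/2} w M / ((1−w) N)`; the outlier weight w defaults
  to 0.
* M-step: `A = Σ P[m,n] x_n y_mᵀ`; SVD `A = U S Vᵀ`;
  `R = U C Vᵀ` with `C = diag(1, 1, det(U Vᵀ))` so R is always a
  proper rotation; then
  `σ² = (Σ_n Pᵀ1 |x_n|² − 2 tr(AᵀR) + Σ_m P1 |y_m|²) / (3 Σ P)`,
  floored at 1e−12.

Iteration stops when the negative log-likelihood of the reference
under the mixture changes by less than `tol = 0.001`, or after
`max_iter = 60` rounds — values strict enough that a ~400-point pair
converges in seconds on one CPU.  σ² is initialized to the mean
squared cross-pair distance divided by 3 (the standard choice).  EM
guarantees the objective is non-increasing, which the tests assert.

The reported error is the mean squared distance between the rotated
moving points and their *hard* correspondents (argmax responsibility
per moving point); a responsibility-weighted soft variant is available
behind `CPDConfig(soft_mse=True)`.  Scale and translation are
deliberately not estimated: inputs are re-centered on their somata, so
the residual error measures branching-pattern difference only.

Preconditions: ≥ 3 points of rank ≥ 2 per cloud; a cloud whose
centroid lies outside its own circumscribed ball cannot contain the
origin and is rejected as not soma-centered.  The pairwise
dissimilarity registers the second minor's cloud to the first's; since
registration is directional, the all-pairs matrix computes both
orientations and averages them into a symmetric matrix with zero
diagonal (failed pairs are imputed as the matrix maximum, with a
warning).  All topological-minor points — not terminals only — enter
the clouds; `max_points` caps cloud size by deterministic subsampling
when archives are dense.

## Embedding, gradient, morphotypes

The symmetric dissimilarity matrix is embedded in 2-D with t-SNE in
precomputed-distance mode (perplexity 30, random initialization, fixed
seed; bit-reproducible for a fixed scikit-learn version).  The
gradient index is the shortest-path distance from a root neuron on a
k-nearest-neighbor graph (k = 10, grown until the graph is connected)
with Euclidean edge weights, divided by the maximum index, so the root
scores 0 and the farthest neuron 1.  The root is the most dorsal
(smallest superior-inferior soma coordinate) neuron whose dominant
target is the barrel field, with lexicographic id tie-break; without
any such neuron the extreme upper-right embedding point is used, with
a warning.  An alternative normalization between the root and an
explicit anchor neuron is exposed (`anchor` handling clips indices
above 1).  Morphotypes come from Ward agglomerative clustering of the
2-D coordinates cut at 3 clusters, renumbered so the mean gradient
index increases with the type label.  Gradient–morphometric
association uses Spearman rank correlation with two-sided p; constant
vectors yield a flagged NaN.

## Topography fit

Each neuron's terminals are summarized by their medoid — the member
point minimizing the summed Euclidean distance to the rest (lowest
index on ties) — so the summary is always a real termination location
even for multi-target arbors.  Somata are fit to medoids by affine
least squares (homogeneous design, needs ≥ 4 non-coplanar pairs) after
rescaling both sets to 10-μm voxel units, which sets the unit of the
reported MSE.  The rotation is read from the 3×3 linear part by polar
decomposition with the same determinant correction as CPD, and
reported as Euler angles — default extrinsic x-y-z, with all 12 proper
conventions available and a search helper for comparing against angles
of unknown convention.  Gimbal lock zeroes the third angle and sets a
flag.  Including the translation in the fit (rather than forcing the
map through the origin) is the standard least-squares reading; the
rotation is unaffected by it.

## Synthetic populations

The generator emulates a first-order sensory relay:

* **Somata** uniform in a nucleus ellipsoid (radii 350 × 320 × 340 μm).
* **Topography**: a fixed affine map `anchor = s·R*·soma + t` with
  scale s = 1.4 and rotation R* given by extrinsic-xyz Euler angles,
  default (−60, 0, −120)°.  The anchor is the center of the neuron's
  primary terminal cluster inside a six-layer cortical slab
  (L1…L6b, 150/300/225/300/300/75 μm) partitioned into six areas along
  the left-right axis in topographic order
  (SSp-bfd, SSp-n, SSs, SSp-ul, SSp-ll, SSp-m).
* **Depth**: the anchor's normalized left-right position in the
  partition, in [0, 1]; it determines the primary area and drives the
  monotone morphology program — arbor width 40 + 180·d μm, ring
  terminal pairs 6 + round(5·d), and (through the geometry) trunk
  length.  The direction from cortex to nucleus is chosen so trunk
  length is, to first order, a linear function of depth, which makes
  the pairwise registration error increase with depth separation.
* **Motifs**: the number of targeted areas is drawn from
  (0.26, 0.53, 0.17, 0.015), renormalized — the monofocal /
  bifurcating / trifurcating / quadrifurcating mix reported for VPM.
  Secondary areas are adjacent in the topographic order (random side),
  so the two pole areas SSp-bfd and SSp-m never co-occur, matching the
  observation that the barrel and mouth representations act as
  opposite topographic extremes.
* **Terminal clusters**: each cluster is the anchor plus symmetric
  ± pairs on rings in the AP–SI plane, with the left-right offset
  exactly zero so a noiseless cluster never crosses an area boundary.
  The primary cluster additionally carries a tight terminal knot
  (within 1.5 μm of the anchor) that outnumbers all secondary
  terminals combined; a convexity argument then pins the neuron's
  terminal medoid to the anchor, so the noiseless soma→medoid fit
  recovers R* exactly.  Terminal anchors keep a guard band
  (max(3σ_noise, 2 voxels)) off area boundaries — discrete
  module-center targeting, as barreloid axons aim at barrel centers —
  enforced by rejection-sampling the soma.
* **Noise**: isotropic Gaussian jitter of terminal points,
  σ = 20 μm by default.
* **Trees** are grown with interior points every 150 μm along trunks
  and recursive binary splits above each cluster, plus a two-point
  dendrite stub, so the topological minor is a genuine reduction.

`monotone_morphology_params()` names the gradient-study condition: a
purely monofocal population, in which morphology is a monotone program
of depth alone.  With random multi-area motifs the morphology is *not*
a function of depth — motif identity adds depth-independent
variability that dominates the pairwise registration error — so
gradient-recovery experiments condition on the monofocal program.

What the generator does **not** emulate: tortuous axon paths and
boutons, realistic branch-order statistics, curved cortical sheets
and columns (areas are box partitions of a slab), registration error
between specimens, reconstruction artifacts (broken or merged
branches), and dendritic morphology beyond a stub.  Passing recovery
tests on these populations therefore demonstrates correctness of the
algorithms under the stated geometric model, not performance on real
archives.

## Problem sizes and numerical choices

Synthetic studies use populations of 50–100 neurons (60 per seed, five
seeds, for the gradient study; 400 for motif-order fractions), toy
atlases at 20 μm voxels, and minor clouds of ~50–120 points, chosen so
each study runs in seconds to a minute on one CPU while leaving the
binomial confidence intervals informative.  Degenerate inputs are
rejected early (collinear clouds, coplanar soma sets, perplexity ≥ n);
ties are always broken deterministically (canonical area order, lowest
index, lexicographic id); every stochastic step takes an explicit
seed, and the pipeline re-run with the same configuration reproduces
its outputs bit-for-bit.

## Known limitations

* The binomial motif null assumes independent area targeting; a null
  conditioned on dominant-target identity would be stricter.
* Border distances are 3-D Euclidean, not geodesic along the cortical
  sheet; on a folded cortex the two differ near sulci.
* t-SNE coordinates are only reproducible for a fixed scikit-learn
  version; the gradient index is more stable than the raw embedding
  but inherits its seed dependence.
* The Euler-angle report depends on the convention; cross-study
  comparisons should use `best_convention_match` or compare rotation
  matrices directly.
* Dense occupancy export at 10 μm is deliberately unsupported
  (~10⁹ voxels per type); occupancy is sparse, and dense export is
  meant for ≥ 25 μm grids.
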