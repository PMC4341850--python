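# Methods

## Pipeline model and assumptions

The package assumes its input is a *binary* segmentation of a tree-shaped
tubular structure (an airway lumen) with strictly positive, possibly
anisotropic voxel spacing, and that the user can point at the tree's
entrance (the coordinate is snapped to the nearest skeleton point). The
object is assumed simply connected — loops in the segmentation are not an
error, but the spanning-tree step will break each loop at its longest
span, so anastomoses are not represented.

### Tri-axial skeleton

Each 2D slice perpendicular to each axis is thinned with Zhang–Suen
morphological thinning (`skimage.morphology.skeletonize`), which preserves
per-slice topology and yields unit-width 8-connected curves. For a tube,
the per-axis stack of slice skeletons approximates a medial surface; the
voxel-wise product (logical AND) of the three axis skeletons approximates
the medial *curve*. Because three independently rounded curves must agree
on a voxel, the product is sparse and disconnected — that is expected, and
the minimum spanning tree over physical Euclidean distances reconnects it.
Prim's algorithm runs on a k-nearest-neighbour candidate graph (default
k = 26); if the candidate graph is disconnected, the globally closest pair
between components is bridged repeatedly before the tree is grown. On
complete graphs of up to 8 points the result is verified against
exhaustive spanning-tree enumeration in the test suite.

### Dominant skeleton

Geodesic distances are computed along tree edges (never through space) by
Dijkstra's algorithm; on a tree the shortest path and hence the
predecessor map is unique. The main airway is the backtracked path to the
point farthest from the seed. Each further branch is extracted with *all*
previously extracted path nodes as distance sources, so a new path touches
the old skeleton only at its connection node — paths are node-disjoint
except at junctions by construction. Extraction stops when the farthest
remaining distance drops below `min_branch_length`; when that parameter is
unset it defaults to 5% of the main-path length. The threshold is read as
an absolute length (a per-generation relative rule would also be
defensible; the absolute rule is the simplest one consistent with
suppressing noise leaves).

### Topology graph and junction merging

The reduced graph keeps the entrance, junctions and path tips; edge
lengths are sums of the underlying skeleton edge weights. Junction pairs
closer (along the graph) than `junction_merge_distance` are contracted,
shortest edge first, to a fixpoint — the operation is idempotent and each
contraction removes exactly one node, so the result stays a tree. The
merged node is placed at the midpoint of the two positions; the contracted
edge's length leaves the total (documented deviation from strict length
conservation). Arc lengths from the entrance are recomputed after merging.

### Features and classifier

`n_d` counts junctions of degree `d` with arc length from the entrance at
most `fraction × main_path_length` (default fraction 0.75). The classifier
models each class as a univariate normal with **population variance**
(divide by n; the convention is not derivable from first principles and is
fixed here), floored at `1e-9·range² + 1e-12` so single-sample classes in
small leave-one-out folds stay well defined, and frequency priors. The
decision threshold solves the quadratic from equating class log densities
plus log priors; with unequal variances the root between the class means
is the operating threshold. Posterior ties predict the first class in
sorted label order. Counts are treated as real-valued for density
evaluation.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| `min_branch_length` | physical length | 5% of main path | suppress noise leaves |
| `junction_merge_distance` | physical length | 3 × mean spacing | merge near-coincident junctions |
| `main_path_fraction` | — | 0.75 | arc-length budget for junction counting |
| `mst_neighbor_count` | — | 26 | MST candidate-graph degree |

Both length parameters must be tuned to the data's noise scale; the merge
distance in particular is determined empirically (for the phantom corpus:
suppression 10 voxels, merge 15 voxels — the scale of junction-localization
error observed at twin-branch sites, kept below a third of the phantom's
inter-site spacing).

## Determinism

Every tie breaks toward the lexicographically smallest voxel index:
skeleton nodes are stored in lexicographic order, so heap entries compare
`(distance, node id)`, the farthest point is the first argmax, and merge
candidates sort by `(length, node pair)`. Phantom generation draws all
randomness from one `numpy.random.default_rng(seed)` stream in a fixed
order. Repeated runs are bit-identical.

## The phantom generator

A phantom emulates a monopodial (rodent-like) airway: a gently curved
trunk — a polyline with sinusoidal lateral offsets of 1.5–3 voxels, both
because real airways curve and because a perfectly straight, nearly
axis-aligned tube is a worst case for the tri-axial product (slice-center
rounding can agree nowhere over long runs) — with lateral branches at
70–85° polar angle from the local trunk tangent,
radius 2.6 voxels tapering by 0.75 per generation, branch lengths 26–34
voxels, three sites at least 45 voxels apart and 20 voxels from either
trunk end. Class A emits single branches; class B emits, with probability
0.8, twin branches on opposite azimuths (a ground-truth 4-junction).
Branch directions are rejection-sampled to keep at least 0.12 of their
magnitude along every grid axis: a straight tube lying exactly in a grid
plane and diagonal within it can disappear from the skeleton product, and
the bound is preserved by axis-aligned rotations and flips. Rasterization
uses capsules (cylinders with spherical caps) so joints are watertight.
Surface noise adds spherical bumps (default radius 1.5 voxels, 0.3 bumps
per 100 surface voxels) at random surface voxels — small relative to every
tube radius, so they perturb the skeleton only by short leaves that the
suppression length removes.

What the phantoms do **not** emulate: imaging point-spread and
reconstruction artifacts, segmentation holes or cavities, touching or
anastomosing branches, diameter irregularity along a branch, and
generation-dependent branching statistics. Tests passing on phantoms
therefore demonstrate the correctness and invariances of the *algorithmic
chain*, not segmentation robustness on real tomograms.

## Numerical notes and known limitations

- Skeleton paths zig-zag across the voxel grid, so measured branch and arc
  lengths exceed the continuous centerline lengths by roughly 5–20%. All
  length thresholds are applied on the measured (graph) scale.
- Junction positions are localized to within a few tube radii; at a twin
  site the two detected connection points can sit up to ~14 voxels apart
  along the skeleton, which is what the phantom merge distance of 15
  absorbs.
- The `fraction` cutoff is a hard boundary: a junction whose arc length
  lies within about a voxel of `fraction × main_path_length` can flip in or
  out under grid transforms or resampling. Invariance of the feature is
  therefore exact at fraction 1.0 and only approximate near a cutoff that
  intersects a junction; cohort analyses should not place the cutoff on
  top of a junction of interest.
- Degree counting starts at 3; an unmerged spurious junction inflates
  `n_3` first, so `n_4` (the class-separating feature here) is relatively
  robust to residual noise.
- The classifier is univariate and two-class by design; multivariate
  features or other cross-validation schemes are out of scope.
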