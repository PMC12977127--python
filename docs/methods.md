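# Methods

This note documents the models and procedures behind foliakit, the defaults
they ship with, the numerical choices that matter, and what the synthetic
phantoms do and do not establish about behavior on real cerebellar data.

## Coordinate and label conventions

Voxel indices are 0-based; the 4×4 affine maps voxel *centers* to world
coordinates in mm (NIfTI convention), so voxel `(i,j,k)` covers the cube of
side `voxel_size` centered on `affine·(i,j,k,1)`. Displacement fields are
stored as 3-component vector volumes in world mm with their own affine.
Label id 0 is background; a negative sentinel (`INTERIOR_SENTINEL = -1`)
marks filled-but-unassigned interior voxels inside pipelines and never
reaches disk. A `LabelTable` carries (id, name, RGB) triples and designates
the white-matter/corpus-medullare id and the white-matter-tract id (the
patch that closes the cortical sheet where the peduncles are cut).

## Winding-number voxelization

A closed, consistently oriented triangle mesh partitions space by its
generalized winding number; we evaluate it exactly as the sum of per-triangle
signed solid angles (Van Oosterom–Strackee), normalized by 4π, and classify
a point as interior when the absolute value is ≥ 0.5. Closedness is checked
combinatorially (every undirected edge in exactly two faces, every directed
edge once); inconsistent orientation or boundary edges raise a topology
error with the offending edge count.

`voxelize_labeled_surface` marks each voxel containing ≥ 1 vertex as a shell
voxel carrying the mode of its contained vertices' labels (ties broken
toward the smallest id, for determinism) and each remaining interior-center
voxel with the sentinel. For efficiency, exterior voxels are pre-screened by
a flood fill from the grid border over a blocking mask rasterized from the
triangle interiors (barycentric sampling at half-voxel spacing); the winding
number itself then decides membership for every remaining candidate center,
so the flood fill never classifies a voxel as interior on its own. Default
voxel size is 1 mm for phantoms; the parameter goes down to the native
resolution of a high-resolution surface (≈ 0.2 mm) when memory allows.

Volume estimates (`enclosed_volume_mm3`) count voxel *centers* strictly
inside the surface. Counting all shell voxels instead would overshoot an
analytic ball by the outer half of the one-voxel skin (≈ 15% at radius
10 mm / 1 mm voxels), which is why the center-based count is the quantity
our accuracy checks use; it sits within ~1% of the analytic ball volume at
that scale.

A caution for oracle comparisons: a tessellated sphere lies strictly inside
its circumsphere, so points in the thin shell between the polyhedron's
inradius and circumradius are legitimately classified "outside" by the
winding test while an analytic `‖p‖ < r` oracle calls them "inside". Tests
exclude that chord skin (width < 0.2% of the radius at subdivision 4).

## Volumetric atlas pipeline

`run_atlas_volume_pipeline` executes, in order: voxelize; expand all surface
labels competitively into the interior (default 7 synchronized iterations,
6-connectivity); relabel the remaining interior as white matter; modal
smoothing of the volume (default 3 iterations, 26-connectivity) with
vertex-containing voxels frozen; expand white matter back into cortical
labels (default 4 iterations, never into vertex-containing voxels); restore
vertex-containing voxels from the surface annotation; expand all
non-white-matter labels once at the expense of white matter; pull voxel
labels onto the vertices; modal surface smoothing (radius 3 edges, 3
iterations — the surface-smoothing filter is not otherwise specified for
this step, so the same modal filter is reused); and a final consistency
pass.

Numerical/design choices:

* **Connectivity** — 6 (face) for expansions keeps growth isotropic in voxel
  steps; 26 for modal smoothing gives stable modes. Both configurable.
* **Synchronized sweeps** — every iteration updates all voxels from the
  previous state, which makes the expansion equivalent to a truncated
  multi-source BFS in which, at equal distance, the smallest label id wins.
  The tests pin this equivalence against an independent relaxation oracle.
* **Background protection** — modal smoothing excludes background from the
  candidate modes and freezes background voxels; without this the outer
  shell erodes and unlabeled voxels appear inside the surface.
* **Consistency pass** — each vertex-containing voxel is set to the mode of
  its contained vertex labels, then every vertex adopts its containing
  voxel's label. When a voxel contains vertices of several labels these two
  requirements cannot both hold for all vertices, so the vertex-side
  reassignment wins for the minority vertices; the pass is then exactly
  idempotent and vertex/voxel agreement is 100% by construction.
* The pipeline has no randomness; `PipelineConfig.random_seed` is reserved.

## Equal-area parcellation

Patch counts per region come from largest-remainder apportionment of
`total_patches × area fraction` (every region gets ≥ 1; remainder ties break
toward the smaller region id). Area fractions use barycentric vertex areas
(each face contributes one third to each corner), with the
white-matter-tract label excludable from the denominator.

Seed spreading interprets "move pointers away from one another" as max–min
repulsion: pointers are visited sequentially in ascending patch id, and each
moves to the same-region neighbor maximizing its minimum distance to the
region's other pointers, staying put absent strict improvement. Distance is
the Euclidean chord in the aligned spherical representation — a monotone
equivalent of arc length. Because a move never decreases the mover's own
minimum distance, the within-region minimum pairwise distance is
non-decreasing sweep over sweep (asserted in tests); distances between
pointers of *different* regions are unconstrained. Default: 100 sweeps,
initial seeds drawn uniformly without replacement per region from a single
integer seed recorded in the output.

Growth is plain multi-source FIFO BFS confined to regions, seeds enqueued in
ascending patch id. Seedless disconnected region components are assigned to
the nearest same-region patch by chord distance, with a warning. The patch
map is then mode-smoothed (radius 3, 3 iterations, region-confined); since
smoothing can fragment or annihilate patches at desk scale, fragments are
reattached to the adjacent same-region patch with the longest shared border
and empty ids dropped before balancing.

Balancing splits patches above 2× the current mean area (two new seeds at
the patch's mutually farthest vertex pair by chord distance, then a two-way
BFS inside the patch) and merges patches below ½ the mean into the
same-region neighbor sharing the most boundary edges. The mean is
recomputed after each batch; each patch (children inherit their parent's
count) undergoes at most 5 operations before one forced final pass splits
all remaining oversize and merges all remaining undersize patches. Patch
ids are relabeled contiguously from 1. The procedure typically lands 10–20%
below the requested patch count — the same direction of shrinkage seen when
such schemes are run at full atlas scale — and never increases the area CV
in our tests.

Scale caveat: modal smoothing with radius 3 is destructive when patches are
only a few dozen vertices. Phantom tests therefore match mesh resolution to
patch count (≈ 100 vertices per patch), which is the same ratio-of-scales
regime as a multi-million-vertex surface with several hundred patches.

## Virtual MRI and diffeomorphic registration

`make_virtual_mri` maps each label to an intensity (defaults: cortex 110,
white matter 250, background 0, arbitrary units), then blurs with a
Gaussian (default σ 0.5 mm) and clips to the map's range.

The builtin registration backend is diffeomorphic demons over a stationary
velocity field: per iteration the moving image is warped through
`exp(v)` (scaling-and-squaring with the step halved until the largest
sub-step is < 0.5 voxel), SSD demons forces are computed per channel with
symmetric gradients and summed over channels, capped at `step_size` voxels,
fluid-smoothed (`update_sigma_mm`), added to `v`, and diffusion-smoothed
(`smoothing_sigma_mm`). A 3-level Gaussian pyramid runs coarse to fine
(default 50/50/30 iterations). Because the returned displacement is the
exponential of a smooth velocity field, its Jacobian determinant is positive
at all interior grid points — verified by finite differences in the tests.
The `lncc` metric option applies local mean/variance normalization (5-voxel
window) before the SSD forces, an equivalent-gradient stand-in for locally
normalized cross-correlation; constant images are rejected under `lncc`
with a pointer to `ssd`. The backend is deterministic. An external-adapter
hook passes the fixed/moving volumes and config to a user callable that may
wrap any registration tool (e.g. symmetric normalization) returning a
displacement field.

Fields follow the image pull-back convention: `register(fixed, moving)`
returns `u` with `moving(x + u(x)) ≈ fixed(x)`. Warping *images* into the
fixed space uses `u` directly; carrying *points* (surface vertices) from
moving to fixed space needs the inverse map, computed by fixed-point
iteration (`v ← −u(x + v)`), which converges because the displacement
gradients are contractions for the smooth fields used here (residual
< 0.1 voxel in tests).

## Two-stage surface reconstruction

Stage 1 registers the atlas label volume to the subject's lobular
segmentation. Labels become a registrable image as per-label one-hot
channels blurred by 1 mm, with demons forces summed over channels — this
keeps every lobule's boundary an explicit gradient rather than collapsing
labels to arbitrary scalar intensities. Stage 2 carries the atlas virtual
MRI through the stage-1 field and registers it to the subject MRI multiplied
by the binary cerebellum mask. The two per-stage inverse fields are applied
to the atlas surface vertices in order; faces, labels and spherical
coordinates pass through unchanged. Subject segmentations are an *input*
(synthetic in all tests); no segmentation model is part of this package.

## Evaluation

Dice uses the convention empty-vs-empty = 1.0 and empty-vs-nonempty = 0.0.
Hierarchies (coarse / lobe / lobule) are disjoint groupings of fine label
ids; a group with no member label present in either volume is reported
missing rather than 0. Hausdorff is the classic symmetric max–min between
voxel-center point sets: for surface-versus-volume comparisons, set A holds
the centers of voxels containing group-labeled vertices and set B the
centers of group-labeled voxels, so the value reflects a surface–volume
discrepancy rather than a boundary-only surface distance. Summaries are
two-stage: per-group medians across subjects, then the unweighted median
and mean over groups, with extremes identified; dispersion uses
median-unbiased quantiles.

## Synthetic phantoms: what they cover and what they do not

`make_folded_phantom` builds a subdivided icosphere with radius
`R(1 + a·sin kθ·sin kφ)` (defaults R = 25 mm, k = 6, a = 0.2, subdivision 5
≈ 10k vertices — large enough to fold, small enough for seconds-scale
tests), equal-area latitude-band labels standing in for lobules, an optional
midline meridian strip standing in for a vermis group, and the unit sphere
as its spherical coordinates. Self-intersection is screened by probing
winding numbers just inside a sample of face centroids. Deformations are
band-limited sinusoid mixtures rescaled so the displacement-gradient norm
stays below 0.9, a sufficient condition for a positive Jacobian. Subjects
are nearest-neighbor (labels) / trilinear (intensities) pull-backs through
a known field plus Gaussian noise. Everything is bit-reproducible from its
spec and seed.

The phantoms exercise closed-surface topology, folding, multi-region
labeling, and known ground-truth deformations. They do not emulate MRI
contrast physics, ex vivo fixation effects, segmentation errors beyond
additive noise, the extreme vertex counts of a real subfolial surface, or
anatomical label geometry (bands are simpler than lobules). Passing tests
therefore demonstrate algorithmic correctness and the advertised invariants
at matched ratios of scale — not clinical-grade reconstruction accuracy on
real data.

## Problem sizes

Defaults used by the test suite and the acceptance script: pipeline
consistency on the ≈10k-vertex default phantom at 1 mm voxels (grid ≈ 62³);
parcellation and registration on the 2562-vertex phantom (registration at
2 mm voxels, grid ≈ 34³, deformation amplitude 6 mm = 3 voxels, noise SD 5
on intensities spanning 0–250). These sizes keep the full suite under two
minutes while leaving every ratio that the algorithms are sensitive to
(voxels per edge length, vertices per patch, deformation amplitude per
voxel) in the regime of the full-scale problem.
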