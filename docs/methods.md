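# Methods

This note documents the models and algorithms implemented in `spineflow`,
the parameter defaults and why they were chosen, what the synthetic
phantoms do and do not emulate, and the numerical conventions that a user
reproducing or extending the package should know.

## Problem setting

The input is a single-channel 3-D confocal stack of an intracellularly
filled neuron (16-bit, strongly anisotropic voxels — the default geometry is
0.0751562 × 0.0751562 × 0.279911 μm) together with, at training time, a
3-class annotation: background (0), dendritic shaft (1), dendritic spine
(2). Two properties of such annotations drive the design. First, experts
reconstruct only selected branches, so correct structures in the image may
be unlabeled (*missing reconstructions*). Second, spine necks are often
thinner than the optical resolution, so annotated structures fall apart
into disconnected voxel components (*unattached components*).

## Voxelization

Closed surface meshes (μm coordinates) are converted to labels in two
steps: every voxel whose axis-aligned physical box intersects a surface
triangle is marked (exact separating-axis triangle/box test, not centroid
sampling), and interior voxels are found by labeling the background
complement with 6-connectivity and keeping components that do not touch the
volume border. Voxels are half-open boxes `[i, i+1)·size`; a polygon lying
exactly on a voxel-boundary plane belongs to the voxel on its inner side
(implemented by shrinking the surface inward by 10⁻⁶ voxel along vertex
normals before the tests). Where shaft and spine claim the same voxel the
spine wins by default — spine surfaces are traced over the shaft and spine
identity is the analysis target — and the per-spine instance volume
returned alongside preserves identity; the opposite policy is available.

**Volume bias.** Marking every colliding box yields the *outer cover* of
the solid: the filled voxel count exceeds the true volume by roughly
(mean box support ≈ 0.75 voxel) × surface area, i.e. about +2.25/r for a
sphere of radius r voxels (+22 % at r = 10, +11 % at r = 20). This is a
property of the marking rule, not an implementation error; the count
converges to the analytic volume from above as resolution grows, with the
error halving per doubling. Users measuring volumes from voxelized labels
should either correct for this bias or measure on the marching-cubes
surface instead.

## Automatic reconnection

A structure (the whole shaft, or one spine) given as a possibly
disconnected voxel set is repaired in five steps:

1. **Clipping** to the structure's bounding box padded by the maximum
   ellipsoid semi-axes, for speed; edits are re-embedded losslessly.
2. **Component detection** (default 26-connectivity, configurable to 6).
3. **Path search**: a path `p` from the detached component to any other
   component of the same structure minimizing
   `Σᵢ (1−den(pᵢ))·f_s + Σᵢ dist(pᵢ₋₁,pᵢ)`, where `den` is the min–max
   normalized intensity of the clip and `dist` the voxel-center distance.
   A\* uses the Euclidean distance transform to the target set as
   heuristic; it is admissible (the density term is non-negative and each
   step costs at least its geometric length), so costs equal Dijkstra's —
   verified exhaustively in the tests. Voxels of *other* structures are
   excluded from the search space. `dist` defaults to physical μm so the
   anisotropic z-step is penalized correctly; a voxel-unit mode is kept for
   ablation. `f_s` defaults to 1.
4. **Median filtering** of the clipped image with an 8 × 8 × 2 voxel
   window. Even window extents are anchored with the extra reach toward the
   positive axis and the upper median (rank n/2) is taken; borders reflect.
5. **Flooding**: every voxel inside the minimum ellipsoid (1 × 1 × 0
   semi-axes: the seed's in-plane cross) around each path voxel is labeled
   unconditionally; from each seed a flood fill adds voxels whose filtered
   intensity lies within ±10 % of *that seed's* intensity, constrained to
   the union of maximum ellipsoids (3 × 3 × 2 voxels for shaft gaps,
   6 × 6 × 2 for spines) and never crossing other structures.

Ellipsoid sizes are per-axis semi-axes in voxels; a zero semi-axis means no
growth along that axis (membership `(dx/a)² + (dy/b)² + (dz/c)² ≤ 1`).
Ground-truth preprocessing applies this first to the shaft, then to each
spine (instances processed independently when identity is known), then
connects still-detached spine components to the shaft, with connector
voxels taking the spine class. Components are traversed largest-first. The
procedure only ever adds voxels, terminates when one component remains (or
no component can be connected, which is reported), and is idempotent.

## Loss functions and weight maps

Training minimizes either the weighted cross-entropy (WCEL)
`−Σₓ w(x) Σₖ rₖ(x) log pₖ(x)` or the generalized Dice loss (GDL)
`1 − 2·Σₖ wₖ Σₓ rₖpₖ / Σₖ wₖ Σₓ (rₖ+pₖ)` with `wₖ = 1/(Σₓ rₖ)²`.
The WCEL weight factorizes as `w = w_class · w_pixel`:

* `w_class` uses the smoothed log-frequency weight
  `w′ₖ = max(log(2·#Ω/#k), 1)`, normalized to sum to 1. Natural logarithm
  throughout. An absent class takes the single-voxel limit
  `w′ₖ = log(2·#Ω)` so that patches without spines remain trainable with
  finite weights. Class counts come from the patch by default or from the
  whole data set (`class_scope="dataset"`).
* `w_pixel` decays with the Euclidean distance `d` (μm, anisotropic,
  computed on the preprocessed labels) to the nearest annotated structure:
  exponentially, `(1−r_decay)^d` with `r_decay = 0.5`, or with the quartic
  window `(1−(d/d_max)²)²` cut off at `d_max = 5 μm`. Both equal 1 on the
  structures and down-weight regions far from any annotation, where
  "background" labels are least trustworthy.

In GDL an absent class is skipped in both sums (standard ε-guard
behavior); `log` arguments are clamped at 1e-12.

## Network

The segmentation model is a 3-D U-Net-style encoder–decoder: per stage two
3³ convolutions + ReLU with channel doubling and 2 × 2 × 2 max pooling
(z-pooling can be disabled for thin stacks), transposed-convolution
upsampling with skip concatenation, and a 1×1×1 three-class softmax head.
The published profile is five stages, 16 base channels, 300 × 300 × 66
input / 116 × 116 × 10 output patches; the package validates the
input→output contract in valid-convolution mode and reports the required
margins when a configuration is inconsistent. In same-convolution mode a
smaller output patch is produced by center-cropping the logits, which gives
tiles real image context: with a context margin at least the receptive
field radius, tiled prediction is bitwise identical to a single pass
(tested). Patch extraction tiles output windows with stride equal to the
output size, pads input context reflectively at borders (zero padding
available), and drops patches with no labeled voxel (or, optionally, less
than 10 % labeled). Augmentation applies random axis flips, in-plane 90°
rotations and small periodic integer translations identically to image,
labels and weights.

Because no deep-learning framework is part of the dependency set, the
layers are implemented directly in NumPy (channels-last, convolutions as 27
strided-slice matrix products) with hand-written backward passes, verified
against finite differences, and an Adam optimizer (β₁ = 0.9, β₂ = 0.999,
ε = 1e-7). Everything is float32 and deterministic per seed. The published
learning rate (1e-7) is kept as the config default for the full-scale
profile; desk-scale runs in this repository use 1e-3, since 1e-7 makes no
visible progress at small scale.

Evaluation restricts all per-class precision/recall/F1 counts to voxels
within 7.58 μm (physical distance) of the ground-truth shaft — the largest
observed spine-to-shaft distance — because annotations outside that band
are unreliable; zero-denominator metrics are reported as 0 and flagged.
Model selection during training retains the epoch with the best masked mean
F1 on held-out validation volumes.

### Desk-scale training profile

The repository's self-contained experiments train a tiny configuration
(2 stages, 8 base channels, same-conv, 32 × 32 × 16 patches, lr 1e-3,
≤ 15 epochs) on 8 default phantoms. The desk-scale profile uses WCEL with
the smoothed class weights, batch size 1 and no augmentation: the small
batch gives the rare spine class enough optimizer steps inside the 15-epoch
budget, and across phantom batches this profile consistently reaches
held-out masked spine F1 ≈ 0.7 (shaft ≈ 0.93) in a few CPU-minutes. The
generalized Dice loss trains faster when it works but is bimodal at this
scale — depending on the data draw the spine class either locks in
(F1 ≈ 0.74) or collapses entirely — and augmentation slows convergence
below the epoch budget; both remain available and unit-tested.

## Postprocessing

* **Noise filter**: a component is deleted iff its minimal voxel-center
  distance (μm) to the nearest shaft component larger than `V_d` exceeds
  `D` *and* its own volume is below `V_s` (defaults D = 3 μm,
  V_d = 0.16 μm³, V_s = 0.024 μm³; component sizes in μm³). When no shaft
  component exceeds `V_d`, every candidate counts as far and the size test
  alone decides.
* **Watershed splitting** of overlapping spines floods the negated
  anisotropy-aware Euclidean distance transform of the instance mask from
  user seeds (an intensity relief is available); the partition covers the
  mask exactly and each seed keeps its tag.
* **Surface extraction** runs marching cubes per instance on the binary
  mask at iso-level 0.5 with physical spacing and no smoothing; masks are
  zero-padded so interior instances yield watertight meshes.
* **Connectivity statistic**: among predicted spine components that share
  at least one voxel with ground-truth spine voxels, those without any
  voxel 26-adjacent to a predicted shaft voxel are counted as unconnected;
  the improvement ratio between two such counts is `100·(before−after)/
  before`, reported to two decimals.

## Synthetic phantoms

A phantom is a tube of radius 0.45 μm around a smooth random polyline
(the shaft) with 8 spines: spherical heads (radius 0.20–0.35 μm) connected
by cylindrical necks of radius 0.075 μm ≈ one in-plane voxel — at the
resolution limit, the hard case the pipeline targets — and length
0.45–0.80 μm. The intensity channel is the structure indicator scaled to
16-bit (peak 20 000), blurred with a separable Gaussian PSF (σxy = 0.1 μm,
σz = 0.3 μm; the 3:1 axial elongation mimics confocal optics) plus additive
Gaussian noise (σ = 600) and optional Poisson noise. Defects:
`neck_break_probability` erases selected spines' necks (and any head voxel
touching the shaft) from the *labels only*, reproducing unattached
components with the neck still faintly visible in the image;
`missing_branch` adds a collateral branch to the image that the labels
omit. Spines are placed with rejection sampling so their rasterized masks
stay separated; failures after bounded retries are reported and skipped.
The generator is bit-deterministic per seed.

What the phantoms do **not** emulate: real dendrite morphology (spine shape
classes, branching shafts), depth-dependent attenuation, realistic photon
statistics, refractive aberrations, or annotation styles of human experts.
Tests passing on phantoms therefore demonstrate algorithmic correctness and
the qualitative behavior of the training strategies, not clinical-grade
segmentation accuracy on real cortex data.

## Scaled-down experiments and their sizes

All self-contained experiments run on one CPU with fixed seeds. Problem
sizes: phantoms 96 × 96 × 32 voxels; reconnection recovery over 20 phantoms
with half the necks broken; network training on 8 phantoms with 2 held out;
the preprocessing-impact replay trains the tiny network on 8 phantoms per
arm (corrupted vs repaired labels, 15 epochs) and compares
unconnected-spine-part counts on 3 held-out phantoms (the test suite runs a
further-reduced 4-phantom / 6-epoch version). The desk-scale outcome is
seed-dependent. When both arms train successfully the full-scale direction
reproduces clearly — e.g. 14 of 26 considered spine parts detached for the
corrupted-GT model against 5 of 25 for the repaired-GT model — because the
corrupted-trained network has learned to leave necks unlabeled. For other
data seeds, training on labels where half the spines are erased can instead
make the rare spine class collapse outright (spine F1 ≈ 0, hence trivially
zero unconnected parts). The replay
therefore reports the counts together with each arm's spine F1 rather than
asserting the count direction; at full scale the corruption is a small
fraction of an abundant class and the published comparison is
well-defined.

## Known limitations

* The NumPy network is CPU-bound and meant for desk-scale experiments;
  full-resolution training at the published patch sizes requires a GPU
  framework implementation of the same architecture.
* Reconnection assumes gaps are bright enough to trace: a neck entirely
  lost to noise yields a geodesic path that may cut corners.
* Mixed precision, V-Net-style residual variants and learned gap closing
  are out of scope.
* Mesh input must be watertight; hole filling is not provided.
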