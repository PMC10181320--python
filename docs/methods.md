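# Methods

`ffnet3d` segments high-resolution 3D plant point clouds into three organ
classes — ground, stem, leaf — with a two-branch network that fuses
voxel-level context and point-level detail.  This note records the model,
the numerical choices behind it, what the synthetic data does and does not
emulate, and the problem sizes the package uses at desk scale.

## The segmentation model

**Why two branches.**  Point networks that rely on KNN neighborhoods scale
as O(N²) and force heavy down-sampling on scans with 10⁵–10⁶ points, which
destroys exactly the thin structures (stems, petioles) that matter for
phenotyping.  Voxel networks keep O(N) neighborhood lookup but quantize
away sub-voxel detail.  The model here runs both representations at once on
the *entire* cloud and learns, per point and per feature channel, how much
to trust each.

**Adaptive voxelization.**  The grid always places a fixed number of voxels
(default 128, 64 in the small desk configuration) along the longest
bounding-box axis, with cubic cells covering the padded box.  A seedling
and the same plant two weeks later therefore occupy the grid at the same
relative resolution — the voxel edge adapts to the plant, not the other
way round.  Cells are half-open `[lo, hi)`; a point exactly on the global
max corner clamps into the last cell so coverage is total.  Anisotropic
(per-axis) voxels are representable in `GridSpec` but cubic cells are the
default; nothing in the pipeline assumes anisotropy.

**Voxel feature encoder.**  Each point contributes a 9-vector
`[p ; p − c(V) ; p − v]` where `c(V)` is the centroid of the points sharing
its voxel and `v` the voxel's minimum corner ("center" is a config
alternative).  A shared two-layer perceptron lifts this to the working
width and an elementwise max over each voxel's members forms the voxel
feature (mean reduction is a config alternative; max is the usual
symmetric-function choice for order-invariant pooling).  The centroid term
is written as a member *mean* rather than a raw sum: a sum of positions
scales with occupancy and is not translation-meaningful, whereas the mean
offset measures where the point sits inside its local point set.

**Sparse U-Net (voxel branch).**  Convolutions are evaluated only at active
sites via rulebooks — per-kernel-offset lists of (input row → output row)
pairs found by exact integer coordinate matching (no lossy hashing; a
wrong-bucket collision would silently corrupt the stencil).  Three modes:
submanifold (stride 1, output sites = input sites, so sparsity never
dilates), strided (output sites = unique `floor(coord/2)`, 2×2×2 window),
and inverse (the stored strided rulebook transposed, which restores the
pre-stride site set exactly — the decoder's site sets are identical to the
encoder's by construction, not approximately).

The encoder stacks four stages of an asymmetric residual block (ASPC)
followed by a stride-2 convolution.  The ASPC block runs two parallel
submanifold paths with plate-shaped kernels — (3,1,3) then (1,3,3), and the
transposed order — summed with an identity shortcut (1×1×1 projection when
widths change).  Plate kernels concentrate parameters on the horizontal
and vertical structures plants are made of (leaf sheets, upright stems) at
roughly a third of the weights of a full 3×3×3 kernel.  Exact kernel
shapes are configurable.  The decoder mirrors the encoder with four ISPC
stages: inverse convolution to the stored site set, skip concatenation,
1×1×1 mix.  Each convolution is followed by per-channel batch
normalization over active sites and a leaky ReLU (slope 0.1); both choices
are conventional and were fixed before any evaluation.

**Point branch.**  A mini-PointNet (shared per-point perceptron, no
cross-point mixing) embeds coordinates normalized to the grid's unit box —
normalization keeps the point branch scale-free across growth stages while
the voxel encoder sees raw coordinates.  One Voxel-PointNet (VPN) block per
encoder stage then gathers that stage's voxel feature to each member point,
concatenates, applies a shared perceptron, and adds a residual shortcut.
Because stage `s` voxels are `2^s` coarser, the four blocks hand each point
a multi-scale context pyramid at O(N) cost — the voxel lookup plays the
role KNN search plays in point networks.

**Attention fusion.**  At full resolution each point holds a voxel-branch
feature `f_v` (decoder output gathered to points) and a point-branch
feature `f_p`.  Each branch's small MLP maps its feature to 2·C scores;
the two score vectors are summed, reshaped to (2, C), and softmaxed over
the branch axis, giving per-channel weights `α_v + α_p = 1`.  The fused
feature `α_v⊙f_v + α_p⊙f_p` is a channelwise convex blend, so every fused
channel is bounded by the two branch values.  A scalar-per-branch variant
(softmax over two scalars) sits behind `attention_mode="scalar"` because
the score width is a genuinely open design choice.

**Heads and loss.**  The point head (shared perceptron → 3 logits) is
supervised with class-weighted cross-entropy; the voxel head (1×1×1
convolution on the decoder output) with class-weighted cross-entropy plus
Lovász-softmax, and the total loss is their plain sum.  Class weights are
reciprocal frequencies computed once over the whole training set (not per
batch) so the loss scale is deterministic; with organ shares around
50/5/45% the stem class is up-weighted ~20×.  Voxel ground truth is the
majority vote of member-point labels, ties broken toward the smaller class
id.  The Lovász term uses the classes-present-in-batch averaging variant,
which is stable when a batch contains few stem voxels.  The sorted-error
permutation and the Jaccard-gradient coefficients are treated as constants
of the backward pass, the standard treatment for this loss.  Cross-entropy
weighting uses the one-hot target reading of the weighted-CE definition.

## Training protocol

Adam, learning rate 0.001 (constant — no schedule), batch size 4 whole
clouds, up to 200 epochs in the full protocol; every cloud is processed at
full resolution with no down-sampling.  Batches are realized as sequential
per-cloud passes with gradients averaged before the optimizer step — with
per-cloud batch-norm statistics this is the natural whole-cloud analogue
of mini-batching and keeps peak memory at one cloud's graph.  Gradients
are clipped at global norm 10 (guarding the NaN-abort path); a non-finite
loss aborts with a diagnostic.  Per-cloud geometry (grids, coarsened
assignments, rulebooks) is precomputed once and reused across epochs since
coordinates never change.  Training is fully deterministic under a fixed
seed: parameter init, cloud shuffling and the generator are all seeded,
and the best-train-mIoU checkpoint round-trips bit-exactly (`np.savez`
with float32 parameters by default; `precision="float64"` is available and
is what the finite-difference tests use).

## Synthetic plants

The generator emulates the features of daily organ-labeled plant scans
that drive the learning problem: a dominant planar ground patch at z = 0;
a thin, slightly bowed vertical stem holding ≈5.5% of the points (the
minority-class share typical of maize scans, the regime the weighted loss
exists for); several curved leaf sheets attached at distinct stem heights,
drooping tip-ward with a shallow cross-section arc — the thin-sheet
geometry that makes leaf-edge/stem confusion hard; optional top "whorl"
cluster reproducing the stems-surrounded-by-leaves failure mode; organ
point counts drawn from a multinomial at target fractions (ground and
leaf split the non-stem mass evenly) to mimic scanner density variation;
isotropic Gaussian coordinate noise (default σ = 1 mm at metre scale);
growth series scaling stem height, leaf length and point budget by
(1+rate)^day.  With zero noise the construction guarantees stem points lie
within the stem radius of the axis and leaves clear the ground plane by
more than a stem radius, so organs never interpenetrate.

What it does *not* emulate: occlusion and self-shadowing, sensor-specific
noise anisotropy, per-leaf instance structure, petioles/fruit, multi-plant
scenes, and registration artifacts.  Passing the held-out-plant harness
therefore shows that the pipeline learns and transfers organ geometry
across plant instances at realistic class imbalance — not that it matches
field performance on real scanner data, which requires the real datasets
and full-scale training.

## Desk-scale problem sizes

The test and reproduction harnesses use sizes chosen so the whole suite
runs on one CPU: the overfit harness trains the small configuration
(stage widths 16/32/32/32, resolution 64) on a single 20 000-point plant
for 300 optimizer steps; the held-out-plant harness trains on eight
6 000-point plants (seeds 0–7) for 30 epochs and evaluates on two unseen
plants (seeds 8–9).  Oracle checks run on grids ≤ 8³ against brute-force
dense convolution, and the Lovász loss is verified against exhaustive
hard-label enumeration at N ≤ 4–6 and a plain-python sorted-error
reference.

## Known limitations

* CPU-only numpy engine: throughput is orders of magnitude below GPU
  sparse-conv frameworks; million-point clouds are out of desk scope.
* Batch-norm statistics come from whole single clouds during training;
  very small clouds (hundreds of points) give noisy statistics.
* The held-out-plant harness measures generalization across synthetic
  instances only (see above).
* No per-leaf instance segmentation — leaf identity is deliberately
  collapsed to one semantic class.
* Translation equivariance of voxel assignment is exact only away from
  cell boundaries; points within float rounding of a face may land in
  either neighboring cell.
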