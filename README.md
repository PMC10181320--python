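# ffnet3d

Semantic segmentation of high-resolution 3D plant point clouds into
**ground / stem / leaf**, for plant-phenotyping pipelines that need
per-organ geometry (leaf area, stem height, growth tracking) from daily
laser or LiDAR scans.

Modern scanners produce clouds with 10⁵–10⁶ points per plant.  Point
networks built on KNN neighborhoods (PointNet++-style) cannot ingest them
without aggressive down-sampling, which destroys the thin stems that are
hardest — and most valuable — to segment.  `ffnet3d` implements a
two-branch point–voxel fusion network that processes the *entire* cloud:

* a **voxel branch**: adaptive voxelization (a fixed voxel count along the
  longest bounding-box axis, so growing plants keep a constant relative
  resolution), a per-point geometric encoder
  `f = MLP([p ; p − centroid(V) ; p − corner(V)])` max-pooled per voxel,
  and a sparse 3D U-Net of asymmetric residual blocks built on a
  from-scratch submanifold / strided / inverse sparse convolution engine;
* a **point branch**: a mini-PointNet over normalized coordinates plus one
  Voxel-PointNet block per encoder stage, treating each (progressively
  coarser) voxel as the point's neighborhood — O(N) context instead of
  O(N²) KNN;
* **attention fusion**: per-channel softmax scores `α_v + α_p = 1` blend
  the two branches, `f̃ = α_v⊙f_v + α_p⊙f_p`, feeding the point
  classification head.

Training uses `Loss = Loss_v + Loss_p`, where the voxel head gets
class-weighted cross-entropy (weights = reciprocal class frequencies,
which up-weights the ~5% stem class ~20×) plus Lovász-softmax — a
differentiable surrogate of 1 − IoU — and the point head gets weighted
cross-entropy.  Evaluation reports per-class IoU = TP/(TP+FN+FP) and mIoU.

Everything runs on numpy via a small built-in reverse-mode autodiff
engine; no GPU or deep-learning framework is required.  A procedural
plant generator (planar ground, bowed cylindrical stem, drooping curved
leaf sheets, realistic class imbalance, growth series) makes the whole
pipeline testable without downloading any dataset.

## Worked example

```bash
# 1. generate a labeled synthetic bundle: 2 plants × 3 daily scans
ffnet3d generate --out bundle.h5 --plants 2 --days 3 --points 8000 --seed 0

# 2. inspect the adaptive voxel grid of one exported cloud
ffnet3d voxelize cloud.txt --resolution 64

# 3. train a small configuration for a few epochs
#    (config.yaml:  model: {voxel_resolution: 64, stage_widths: [16, 32, 32, 32],
#                           epochs: 30, batch_size: 4})
ffnet3d train --data bundle.h5 --config config.yaml --out-dir run --seed 0

# 4. evaluate the retained best checkpoint
ffnet3d evaluate run/best.npz --data bundle.h5

# 5. predict labels for a new cloud (text or PLY)
ffnet3d predict run/best.npz cloud.txt --out labeled.txt
```

The same flow from Python, on the library API:

```python
import numpy as np
from ffnet3d import (PlantRecipe, generate_plant, DatasetBundle,
                     ModelConfig, RunConfig, train, evaluate_bundle)

clouds, split = [], {}
for s in range(4):
    c = generate_plant(PlantRecipe(n_points_target=6000, seed=s))
    c.plant_id = f"plant{s}"; split[c.plant_id] = "train"; clouds.append(c)
bundle = DatasetBundle(clouds=clouds[:3], split=split)
held_out = DatasetBundle(clouds=clouds[3:], split=split)

cfg = RunConfig(model=ModelConfig(voxel_resolution=64, epochs=20,
                                  batch_size=3, seed=0), out_dir="run")
model, log = train(bundle, cfg, log_fn=None)
report = evaluate_bundle(model, held_out)
print(report.format_table())
```

prints

```
mIoU    Ground  Stem    Leaf
79.77   98.65   50.39   90.26
```

— the mean and per-class intersection-over-union on the held-out plant, in
percent: ground is nearly perfect (it is planar and separable), the
minority stem class is the hard one (it holds ~5% of the points), and the
mIoU averages the three.  Longer training and more training plants push
the hold-out mIoU above 90 (the reproduction harness below trains on eight
plants for 30 epochs).

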