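"""The two-branch point–voxel fusion segmentation network.

The voxel branch voxelizes the cloud adaptively, encodes each point's
geometry relative to its voxel (position, offset from the voxel's member
centroid, offset from the voxel's corner), max-pools those per-point codes
into voxel features, and runs a sparse U-Net of asymmetric residual blocks.
The point branch applies a shared per-point perceptron and refines it with
one Voxel-PointNet block per encoder stage, each treating the stage's
(progressively coarser) voxels as the point's neighborhood.  A per-channel
attention softmax blends the two branches into the fused per-point features
that feed the point classification head; a parallel voxel head supervises
the decoder output.

The whole cloud is processed at once — no down-sampling — which is the
point of the voxel lookup: neighborhood search is O(N) instead of the
O(N²) of KNN-based point networks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import (
    MLP,
    Linear,
    Module,
    Tensor,
    as_tensor,
    concat,
    init_rng,
    leaky_relu,
    softmax,
    use_dtype,
)
from .io import LabeledPointCloud
from .sparse import UNetPlan, VoxelUNet, build_unet_plan
from .voxelgrid import (
    VoxelAssignment,
    assign,
    coarsen,
    fit_grid,
    gather,
    scatter_max,
    scatter_mean,
)

__all__ = [
    "ModelConfig",
    "Preprocessed",
    "VoxelFeatureEncoder",
    "MiniPointNet",
    "VPNBlock",
    "AttentionFusion",
    "FFNet",
    "predict_labels",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    Defaults are the desk-scale configuration: voxel resolution 64 along
    the longest axis, base width 16.  The training protocol follows the
    usual Adam recipe (lr 0.001) with whole-cloud batches.
    """

    num_classes: int = 3
    voxel_resolution: int = 64
    pad: float = 0.0
    encoder_channels: int = 16           # Eq.-style voxel feature width
    stage_widths: tuple[int, ...] = (16, 32, 32, 32)
    point_channels: int = 16
    attention_hidden: int = 16
    attention_mode: str = "vector"       # or "scalar": one score per branch
    voxel_reduce: str = "max"            # or "mean"
    voxel_corner: str = "min"            # or "center": the v_i reference
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 4
    precision: str = "float32"           # network dtype; float64 optional

    def __post_init__(self):
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")
        if self.num_classes < 2:
            raise ValueError("num_classes must be ≥ 2")
        if any(w <= 0 for w in self.stage_widths) or self.point_channels <= 0:
            raise ValueError("channel widths must be positive")
        if self.attention_mode not in ("vector", "scalar"):
            raise ValueError("attention_mode must be 'vector' or 'scalar'")
        if self.voxel_reduce not in ("max", "mean"):
            raise ValueError("voxel_reduce must be 'max' or 'mean'")
        if self.voxel_corner not in ("min", "center"):
            raise ValueError("voxel_corner must be 'min' or 'center'")


@dataclass
class Preprocessed:
    """Per-cloud geometry reused across optimizer steps (coords are fixed,
    so grids, coarsened assignments and rulebooks never change)."""

    cloud: LabeledPointCloud
    assignment: VoxelAssignment
    stage_assignments: list[VoxelAssignment]
    plan: UNetPlan
    encoder_input: np.ndarray   # N×9
    norm_coords: np.ndarray     # N×3 in the grid's unit box


class VoxelFeatureEncoder(Module):
    """Per-point geometric code → shared 2-layer perceptron → voxel pool.

    The code concatenates the point position, its offset from the centroid
    of the points sharing its voxel, and its offset from the voxel's
    reference corner — 9 numbers describing where the point sits globally,
    within its local point set, and within its cell.
    """

    def __init__(self, c_out: int, rng: np.random.Generator):
        self.mlp = MLP([9, c_out, c_out], rng)

    @staticmethod
    def build_input(cloud_coords: np.ndarray, assignment: VoxelAssignment,
                    corner: str = "min") -> np.ndarray:
        p2v = assignment.point_to_voxel
        sums = np.zeros((assignment.n_voxels, 3))
        np.add.at(sums, p2v, cloud_coords)
        centroid = sums / assignment.counts[:, None]
        spec = assignment.spec
        corners = spec.origin + assignment.active_coords * spec.voxel_size
        if corner == "center":
            corners = corners + spec.voxel_size / 2
        return np.concatenate(
            [
                cloud_coords,
                cloud_coords - centroid[p2v],
                cloud_coords - corners[p2v],
            ],
            axis=1,
        )

    def __call__(self, encoder_input: np.ndarray,
                 assignment: VoxelAssignment,
                 reduce: str = "max") -> Tensor:
        per_point = self.mlp(Tensor(encoder_input))
        if reduce == "mean":
            return scatter_mean(per_point, assignment)
        return scatter_max(per_point, assignment)


class MiniPointNet(Module):
    """Shared per-point perceptron on normalized coordinates.

    Purely pointwise — no cross-point mixing; voxel context reaches the
    point branch only through the VPN blocks.
    """

    def __init__(self, c_out: int, rng: np.random.Generator):
        self.mlp = MLP([3, c_out, c_out], rng)

    def __call__(self, norm_coords: np.ndarray) -> Tensor:
        return self.mlp(Tensor(norm_coords))


class VPNBlock(Module):
    """Voxel-PointNet block: the stage's voxel is the point's neighborhood.

    Gathers the stage's voxel feature to each member point, concatenates it
    with the incoming point feature, applies a shared perceptron, and adds
    a residual shortcut.
    """

    def __init__(self, c_voxel: int, c_point: int, rng: np.random.Generator):
        self.mlp = MLP([c_voxel + c_point, c_point], rng)

    def __call__(self, point_feats: Tensor, stage_voxel_feats: Tensor,
                 stage_assignment: VoxelAssignment) -> Tensor:
        if stage_voxel_feats.data.shape[0] != stage_assignment.n_voxels:
            raise ValueError("stage grid does not match stage assignment")
        context = gather(stage_voxel_feats, stage_assignment)
        return self.mlp(concat([point_feats, context], axis=1)) + point_feats


class AttentionFusion(Module):
    """Per-channel convex blend of the two branch features.

    Each branch has its own small perceptron producing 2·C scores (or 2 in
    scalar mode); the branch scores are summed, reshaped to (2, C), and
    softmaxed over the branch axis, giving weights α_v + α_p = 1 per
    channel.  The fused feature is α_v⊙f_v + α_p⊙f_p, so every fused
    channel lies between the two branch values.
    """

    def __init__(self, c: int, hidden: int, rng: np.random.Generator,
                 mode: str = "vector"):
        self.c = c
        self.mode = mode
        out = 2 * c if mode == "vector" else 2
        self.mlp_v = MLP([c, hidden, out], rng, final_plain=True, norm=False)
        self.mlp_p = MLP([c, hidden, out], rng, final_plain=True, norm=False)

    def scores(self, f_v: Tensor, f_p: Tensor) -> Tensor:
        logits = self.mlp_v(f_v) + self.mlp_p(f_p)
        n = logits.data.shape[0]
        width = self.c if self.mode == "vector" else 1
        return softmax(logits.reshape(n, 2, width), axis=1)

    def __call__(self, f_v, f_p) -> Tensor:
        f_v, f_p = as_tensor(f_v), as_tensor(f_p)
        if f_v.data.shape != f_p.data.shape:
            raise ValueError("branch feature shapes must match")
        alpha = self.scores(f_v, f_p)
        a_v = alpha[:, 0, :]
        a_p = alpha[:, 1, :]
        return a_v * f_v + a_p * f_p


class FFNet(Module):
    """Full network; see the module docstring for the data flow."""

    def __init__(self, config: ModelConfig):
        self.config = config
        with use_dtype(config.precision):
            self._build(init_rng(config.seed))

    def _build(self, rng: np.random.Generator):
        config = self.config
        c0 = config.encoder_channels
        cp = config.point_channels
        widths = list(config.stage_widths)
        self.encoder = VoxelFeatureEncoder(c0, rng)
        self.unet = VoxelUNet(c0, widths, rng)
        self.pointnet = MiniPointNet(cp, rng)
        self.vpn = [VPNBlock(w, cp, rng) for w in widths]
        self.voxel_to_point = (
            Linear(widths[0], cp, rng) if widths[0] != cp else None
        )
        self.fusion = AttentionFusion(cp, config.attention_hidden, rng,
                                      mode=config.attention_mode)
        self.point_head = MLP([cp, cp, config.num_classes], rng,
                              final_plain=True)
        self.voxel_head = Linear(widths[0], config.num_classes, rng)

    # -- geometry ------------------------------------------------------
    def preprocess(self, cloud: LabeledPointCloud) -> Preprocessed:
        spec = fit_grid(cloud, self.config.voxel_resolution, self.config.pad)
        assignment = assign(cloud, spec)
        stage_assignments = [assignment]
        for _ in range(self.unet.n_stages - 1):
            stage_assignments.append(coarsen(stage_assignments[-1], 2))
        plan = build_unet_plan(assignment.active_coords, self.unet.n_stages)
        enc_in = VoxelFeatureEncoder.build_input(
            cloud.coords, assignment, self.config.voxel_corner
        )
        box = spec.dims * spec.voxel_size
        norm = (cloud.coords - spec.origin) / box
        return Preprocessed(
            cloud=cloud,
            assignment=assignment,
            stage_assignments=stage_assignments,
            plan=plan,
            encoder_input=enc_in,
            norm_coords=norm,
        )

    # -- forward -------------------------------------------------------
    def forward(
        self, inputs: LabeledPointCloud | Preprocessed
    ) -> tuple[Tensor, Tensor, VoxelAssignment]:
        pre = inputs if isinstance(inputs, Preprocessed) \
            else self.preprocess(inputs)
        with use_dtype(self.config.precision):
            return self._forward(pre)

    def _forward(self, pre: Preprocessed):
        voxel_in = self.encoder(pre.encoder_input, pre.assignment,
                                self.config.voxel_reduce)
        voxel_out, stage_feats = self.unet(voxel_in, pre.plan)
        point_feats = self.pointnet(pre.norm_coords)
        for s, block in enumerate(self.vpn):
            point_feats = block(point_feats, stage_feats[s],
                                pre.stage_assignments[s])
        f_v = gather(voxel_out, pre.assignment)
        if self.voxel_to_point is not None:
            f_v = leaky_relu(self.voxel_to_point(f_v))
        fused = self.fusion(f_v, point_feats)
        point_logits = self.point_head(fused)
        voxel_logits = self.voxel_head(voxel_out)
        return point_logits, voxel_logits, pre.assignment

    __call__ = forward


def predict_labels(point_logits) -> np.ndarray:
    """Per-row argmax; ties break toward the lowest class index."""
    data = point_logits.data if isinstance(point_logits, Tensor) \
        else np.asarray(point_logits)
    return data.argmax(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FFNet, path) -> None:
    """Single-file archive of every named parameter/buffer + the config."""
    arrays = model.named_arrays()
    arrays.pop("config", None)
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> FFNet:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_json)
        cfg_dict["stage_widths"] = tuple(cfg_dict["stage_widths"])
        config = ModelConfig(**cfg_dict)
        model = FFNet(config)
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    with use_dtype(config.precision):
        model.load_arrays(arrays)
    return model
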