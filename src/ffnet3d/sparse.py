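"""Submanifold / strided / inverse sparse 3D convolution, from scratch.

Convolution is evaluated only at active voxel sites.  A :class:`Rulebook`
lists, for every kernel offset, the (input row → output row) pairs that
offset contributes; :func:`sparse_conv` then reduces to a handful of
gather–matmul–scatter passes, which keeps the whole engine differentiable
through the autodiff tape.

Three modes:

* ``submanifold`` — output sites equal input sites, so sparsity never
  dilates through deep stacks (stride 1, odd kernels, centered offsets);
* ``strided`` — output sites are the unique ``floor(coord / stride)`` sites;
  offsets are window-aligned (``in = out·stride + offset``);
* ``inverse`` — the transpose of a stored strided rulebook: features flow
  from the coarse sites back to the exact pre-stride site set, which is what
  lets the decoder restore the encoder's active-site sets bit-for-bit.

Site matching uses an exact integer coordinate encoding (no lossy hashing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    BatchNorm,
    Linear,
    Module,
    Tensor,
    as_tensor,
    concat,
    gather_rows,
    leaky_relu,
    scatter_add_rows,
)
from .voxelgrid import SparseGrid

__all__ = [
    "Rulebook",
    "ConvParams",
    "build_rulebook",
    "sparse_conv",
    "SubmConv",
    "ASPCBlock",
    "ISPCBlock",
    "VoxelUNet",
    "UNetPlan",
    "build_unet_plan",
]


@dataclass
class Rulebook:
    """Kernel-offset → (input row, output row) pair lists."""

    kernel_shape: tuple[int, int, int]
    stride: tuple[int, int, int]
    mode: str
    offsets: np.ndarray              # K×3 integer offsets, np.ndindex order
    pairs: list[tuple[np.ndarray, np.ndarray]]  # per offset: (in_idx, out_idx)
    in_coords: np.ndarray            # M×3
    out_coords: np.ndarray           # M'×3

    @property
    def kernel_volume(self) -> int:
        return int(np.prod(self.kernel_shape))


@dataclass
class ConvParams(Module):
    """K×Cin×Cout weights (K = kernel volume) plus optional Cout bias."""

    weights: Tensor
    bias: Tensor | None = None

    @staticmethod
    def init(kernel_volume: int, c_in: int, c_out: int,
             rng: np.random.Generator, bias: bool = True) -> "ConvParams":
        fan_in = kernel_volume * c_in
        bound = 1.0 / np.sqrt(fan_in)
        w = Tensor(rng.uniform(-bound, bound, (kernel_volume, c_in, c_out)),
                   requires_grad=True)
        b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        return ConvParams(weights=w, bias=b)


def _encode(coords: np.ndarray, base: int, shift: int) -> np.ndarray:
    c = coords.astype(np.int64) + shift
    return (c[:, 0] * base + c[:, 1]) * base + c[:, 2]


def build_rulebook(
    in_coords: np.ndarray,
    kernel_shape,
    stride=1,
    mode: str = "submanifold",
    prior: Rulebook | None = None,
) -> Rulebook:
    """Enumerate the (input, output) site pairs for one convolution.

    ``prior`` is required in ``inverse`` mode and must be the rulebook of the
    matching strided (encoder) convolution; its pairs are transposed.
    """
    in_coords = np.asarray(in_coords, dtype=np.int64)
    if in_coords.ndim != 2 or in_coords.shape[1] != 3:
        raise ValueError("in_coords must be M×3")
    kernel_shape = tuple(int(k) for k in np.broadcast_to(kernel_shape, 3))
    stride = tuple(int(s) for s in np.broadcast_to(stride, 3))
    if any(k < 1 for k in kernel_shape):
        raise ValueError("kernel_shape components must be ≥ 1")
    if any(s < 1 for s in stride):
        raise ValueError("stride components must be ≥ 1")

    if mode == "inverse":
        if prior is None:
            raise ValueError("inverse mode requires the forward rulebook")
        return Rulebook(
            kernel_shape=prior.kernel_shape,
            stride=prior.stride,
            mode="inverse",
            offsets=prior.offsets,
            pairs=[(o.copy(), i.copy()) for i, o in prior.pairs],
            in_coords=prior.out_coords,
            out_coords=prior.in_coords,
        )

    offsets = np.array(list(np.ndindex(kernel_shape)), dtype=np.int64)
    if mode == "submanifold":
        if stride != (1, 1, 1):
            raise ValueError("submanifold mode requires stride 1")
        if any(k % 2 == 0 for k in kernel_shape):
            raise ValueError("submanifold mode requires odd kernels")
        offsets = offsets - np.asarray(kernel_shape, dtype=np.int64) // 2
        out_coords = in_coords
    elif mode == "strided":
        out_coords = np.unique(
            in_coords // np.asarray(stride, dtype=np.int64), axis=0
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    shift = int(max(kernel_shape)) + 1
    base = int(in_coords.max(initial=0)) + 2 * shift + 2
    order = np.argsort(
        _encode(in_coords, base, shift), kind="stable"
    ).astype(np.int64)
    in_codes_sorted = _encode(in_coords, base, shift)[order]

    stride_arr = np.asarray(stride, dtype=np.int64)
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for off in offsets:
        if mode == "submanifold":
            query = out_coords + off          # in = out + centered offset
        else:
            query = out_coords * stride_arr + off  # in = out·stride + offset
        codes = _encode(query, base, shift)
        pos = np.searchsorted(in_codes_sorted, codes)
        pos_c = np.minimum(pos, len(in_codes_sorted) - 1)
        found = (
            in_codes_sorted[pos_c] == codes
            if len(in_codes_sorted)
            else np.zeros(len(codes), bool)
        )
        out_idx = np.nonzero(found)[0].astype(np.int64)
        in_idx = order[pos_c[found]]
        pairs.append((in_idx, out_idx))
    return Rulebook(
        kernel_shape=kernel_shape,
        stride=stride,
        mode=mode,
        offsets=offsets,
        pairs=pairs,
        in_coords=in_coords,
        out_coords=out_coords,
    )


def sparse_conv(features, rulebook: Rulebook, params: ConvParams) -> Tensor:
    """``out[o] = bias + Σ_k Σ_{(i→o)∈pairs[k]} features[i] · weights[k]``."""
    x = as_tensor(features)
    if x.data.shape[0] != rulebook.in_coords.shape[0]:
        raise ValueError("feature rows must match rulebook input sites")
    if params.weights.data.shape[0] != rulebook.kernel_volume:
        raise ValueError("weights kernel volume mismatch")
    if params.weights.data.shape[1] != x.data.shape[1]:
        raise ValueError("weights input-channel mismatch")
    n_out = rulebook.out_coords.shape[0]
    c_out = params.weights.data.shape[2]
    out: Tensor | None = None
    for k, (in_idx, out_idx) in enumerate(rulebook.pairs):
        if len(in_idx) == 0:
            continue
        wk = params.weights[k]  # Cin×Cout slice, differentiable
        contrib = gather_rows(x, in_idx) @ wk
        term = scatter_add_rows(contrib, out_idx, n_out)
        out = term if out is None else out + term
    if out is None:
        out = Tensor(np.zeros((n_out, c_out), dtype=x.data.dtype))
    if params.bias is not None:
        out = out + params.bias
    return out


# ---------------------------------------------------------------------------
# layers / blocks
# ---------------------------------------------------------------------------

class SubmConv(Module):
    """One sparse convolution layer with optional norm + nonlinearity."""

    def __init__(self, c_in: int, c_out: int, kernel_shape,
                 rng: np.random.Generator, norm: bool = True,
                 act: bool = True):
        kv = int(np.prod(np.broadcast_to(kernel_shape, 3)))
        self.kernel_shape = tuple(int(k) for k in
                                  np.broadcast_to(kernel_shape, 3))
        self.params = ConvParams.init(kv, c_in, c_out, rng)
        self.bn = BatchNorm(c_out) if norm else None
        self.act = act

    def __call__(self, features, rulebook: Rulebook) -> Tensor:
        y = sparse_conv(features, rulebook, self.params)
        if self.bn is not None:
            y = self.bn(y)
        if self.act:
            y = leaky_relu(y)
        return y


#: the two asymmetric submanifold kernels used by the residual block —
#: flat-in-y and flat-in-x plates that track the horizontal/vertical
#: structures (leaf sheets, stems) of a plant.
ASPC_KERNELS = ((3, 1, 3), (1, 3, 3))


class ASPCBlock(Module):
    """Asymmetric residual block on a fixed active-site set.

    Two parallel submanifold paths — (3,1,3)→(1,3,3) and (1,3,3)→(3,1,3) —
    each conv followed by batch norm (a leaky ReLU between the two convs of
    a path), summed together with an identity shortcut (1×1×1 projection
    when the channel count changes).  With all conv weights zero the block
    reduces exactly to the shortcut.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        ka, kb = ASPC_KERNELS
        self.conv_a1 = SubmConv(c_in, c_out, ka, rng, act=True)
        self.conv_a2 = SubmConv(c_out, c_out, kb, rng, act=False)
        self.conv_b1 = SubmConv(c_in, c_out, kb, rng, act=True)
        self.conv_b2 = SubmConv(c_out, c_out, ka, rng, act=False)
        self.proj = Linear(c_in, c_out, rng, bias=False) \
            if c_in != c_out else None

    def __call__(self, features, rb_a: Rulebook, rb_b: Rulebook) -> Tensor:
        x = as_tensor(features)
        a = self.conv_a2(self.conv_a1(x, rb_a), rb_b)
        b = self.conv_b2(self.conv_b1(x, rb_b), rb_a)
        shortcut = self.proj(x) if self.proj is not None else x
        return a + b + shortcut


class ISPCBlock(Module):
    """Decoder block: inverse conv to the encoder's site set + skip fusion.

    The inverse convolution restores the exact pre-stride active sites; the
    skip features from the matching encoder stage are concatenated and mixed
    by a 1×1×1 submanifold convolution (a shared per-site linear map).
    """

    def __init__(self, c_coarse: int, c_skip: int, c_out: int,
                 rng: np.random.Generator):
        kv = 8  # matches the 2×2×2 stride-2 encoder window
        self.up = ConvParams.init(kv, c_coarse, c_out, rng)
        self.bn_up = BatchNorm(c_out)
        self.mix = Linear(c_out + c_skip, c_out, rng)
        self.bn_mix = BatchNorm(c_out)

    def __call__(self, coarse_features, skip_features,
                 inverse_rulebook: Rulebook) -> Tensor:
        up = sparse_conv(coarse_features, inverse_rulebook, self.up)
        up = leaky_relu(self.bn_up(up))
        skip = as_tensor(skip_features)
        if up.data.shape[0] != skip.data.shape[0]:
            raise ValueError("restored sites do not match the skip grid")
        y = self.mix(concat([up, skip], axis=1))
        return leaky_relu(self.bn_mix(y))


# ---------------------------------------------------------------------------
# U-Net assembly
# ---------------------------------------------------------------------------

@dataclass
class UNetPlan:
    """Precomputed per-level geometry for one cloud.

    Built once per cloud and reused across optimizer steps: level-wise active
    coordinates, the two asymmetric submanifold rulebooks per level, the
    stride-2 rulebooks between levels, and their transposes for the decoder.
    """

    level_coords: list[np.ndarray] = field(default_factory=list)
    subm_a: list[Rulebook] = field(default_factory=list)
    subm_b: list[Rulebook] = field(default_factory=list)
    down: list[Rulebook] = field(default_factory=list)
    up: list[Rulebook] = field(default_factory=list)


def build_unet_plan(coords: np.ndarray, n_stages: int = 4) -> UNetPlan:
    plan = UNetPlan()
    ka, kb = ASPC_KERNELS
    cur = np.asarray(coords, dtype=np.int64)
    for _ in range(n_stages):
        plan.level_coords.append(cur)
        plan.subm_a.append(build_rulebook(cur, ka, 1, "submanifold"))
        plan.subm_b.append(build_rulebook(cur, kb, 1, "submanifold"))
        rb_down = build_rulebook(cur, (2, 2, 2), (2, 2, 2), "strided")
        plan.down.append(rb_down)
        plan.up.append(build_rulebook(cur, (2, 2, 2), (2, 2, 2),
                                      "inverse", prior=rb_down))
        cur = rb_down.out_coords
    plan.level_coords.append(cur)
    plan.subm_a.append(build_rulebook(cur, ka, 1, "submanifold"))
    plan.subm_b.append(build_rulebook(cur, kb, 1, "submanifold"))
    return plan


class VoxelUNet(Module):
    """Encoder–decoder over active voxels.

    ``n_stages`` encoder stages of (ASPC block → stride-2 strided conv),
    an ASPC bottleneck, then ``n_stages`` ISPC decoder stages consuming the
    stored inverse rulebooks and skip features.  Returns the full-resolution
    features plus the per-stage encoder grids for the point-branch taps.
    """

    def __init__(self, c_in: int, stage_widths: list[int],
                 rng: np.random.Generator):
        if len(stage_widths) < 1:
            raise ValueError("need at least one stage width")
        self.stage_widths = list(stage_widths)
        widths = [c_in] + list(stage_widths)
        self.aspc = [
            ASPCBlock(widths[s], widths[s + 1], rng)
            for s in range(len(stage_widths))
        ]
        self.down = [
            SubmConv(w, w, (2, 2, 2), rng) for w in stage_widths
        ]
        self.bottleneck = ASPCBlock(stage_widths[-1], stage_widths[-1], rng)
        self.ispc = [
            ISPCBlock(
                c_coarse=stage_widths[s + 1] if s + 1 < len(stage_widths)
                else stage_widths[-1],
                c_skip=stage_widths[s],
                c_out=stage_widths[s],
                rng=rng,
            )
            for s in range(len(stage_widths))
        ]

    @property
    def n_stages(self) -> int:
        return len(self.stage_widths)

    def __call__(
        self, features, plan: UNetPlan
    ) -> tuple[Tensor, list[Tensor]]:
        x = as_tensor(features)
        skips: list[Tensor] = []
        stage_feats: list[Tensor] = []
        for s in range(self.n_stages):
            x = self.aspc[s](x, plan.subm_a[s], plan.subm_b[s])
            skips.append(x)
            stage_feats.append(x)
            x = self.down[s](x, plan.down[s])
        x = self.bottleneck(x, plan.subm_a[-1], plan.subm_b[-1])
        for s in reversed(range(self.n_stages)):
            x = self.ispc[s](x, skips[s], plan.up[s])
        return x, stage_feats

    def forward_grid(
        self, grid: SparseGrid, plan: UNetPlan
    ) -> tuple[SparseGrid, list[SparseGrid]]:
        """Grid-in/grid-out variant: wraps features with their coordinates
        and per-level grid geometry."""
        from .voxelgrid import GridSpec

        if grid.coords.shape[0] != plan.level_coords[0].shape[0]:
            raise ValueError("grid does not match the plan's level-0 sites")
        out, stage_feats = self(grid.features, plan)
        spec = grid.spec

        def level_spec(s: int) -> GridSpec:
            f = 2 ** s
            return GridSpec(origin=spec.origin,
                            voxel_size=spec.voxel_size * f,
                            dims=-(-spec.dims // f))

        stages = [
            SparseGrid(coords=plan.level_coords[s], features=feats,
                       spec=level_spec(s), level=grid.level + s)
            for s, feats in enumerate(stage_feats)
        ]
        full = SparseGrid(coords=plan.level_coords[0], features=out,
                          spec=spec, level=grid.level)
        return full, stages
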