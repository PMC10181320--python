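"""Sparse convolution engine vs. brute-force dense oracles."""

import numpy as np
import pytest

from conftest import random_occupancy
from ffnet3d.autodiff import Tensor, init_rng
from ffnet3d.sparse import (
    ASPCBlock,
    ConvParams,
    ISPCBlock,
    VoxelUNet,
    build_rulebook,
    build_unet_plan,
    sparse_conv,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def dense_reference(coords, feats, weights, bias, kernel, mode, stride=1,
                    dim=8):
    """Triple-loop dense 3D convolution restricted to the active output
    sites — the independent ground truth for every sparse mode."""
    kernel = np.broadcast_to(kernel, 3)
    occ = np.zeros((dim, dim, dim), dtype=bool)
    dense = np.zeros((dim, dim, dim, feats.shape[1]))
    for c, f in zip(coords, feats):
        occ[tuple(c)] = True
        dense[tuple(c)] = f
    if mode == "submanifold":
        out_coords = coords
    else:
        out_coords = np.unique(coords // stride, axis=0)
    c_out = weights.shape[2]
    out = np.zeros((len(out_coords), c_out))
    for o, oc in enumerate(out_coords):
        acc = np.zeros(c_out) if bias is None else bias.copy()
        k = 0
        for dx in range(kernel[0]):
            for dy in range(kernel[1]):
                for dz in range(kernel[2]):
                    if mode == "submanifold":
                        ic = oc + np.array([dx, dy, dz]) - kernel // 2
                    else:
                        ic = oc * stride + np.array([dx, dy, dz])
                    if (ic >= 0).all() and (ic < dim).all() and occ[tuple(ic)]:
                        acc = acc + dense[tuple(ic)] @ weights[k]
                    k += 1
        out[o] = acc
    return out_coords, out


def rulebook_pairs_bruteforce(coords, kernel):
    """Enumerate submanifold pairs by scanning all coordinate pairs."""
    kernel = np.asarray(kernel)
    half = kernel // 2
    pairs = {}
    lookup = {tuple(c): i for i, c in enumerate(coords)}
    for k, off in enumerate(np.ndindex(*kernel)):
        delta = np.array(off) - half
        plist = []
        for o, oc in enumerate(coords):
            src = tuple(oc + delta)
            if src in lookup:
                plist.append((lookup[src], o))
        pairs[k] = sorted(plist)
    return pairs


# ---------------------------------------------------------------------------
# rulebook construction
# ---------------------------------------------------------------------------

class TestBuildRulebook:
    def test_single_site_only_center_pair(self):
        rb = build_rulebook(np.array([[2, 2, 2]]), (3, 3, 3))
        n_pairs = [len(i) for i, _ in rb.pairs]
        assert sum(n_pairs) == 1
        center = 13  # offset (0,0,0) in 3×3×3 ndindex order
        assert n_pairs[center] == 1

    def test_two_adjacent_sites_1d_kernel(self):
        coords = np.array([[1, 0, 0], [2, 0, 0]])
        rb = build_rulebook(coords, (3, 1, 1))
        total = sum(len(i) for i, _ in rb.pairs)
        assert total == 4  # each site: itself + its neighbor

    def test_submanifold_sites_preserved(self):
        rng = np.random.default_rng(1)
        coords = random_occupancy(rng)
        rb = build_rulebook(coords, (3, 3, 3))
        assert rb.out_coords is coords or np.array_equal(rb.out_coords,
                                                         coords)

    def test_pairs_match_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        coords = random_occupancy(rng, dim=6, p=0.3)
        rb = build_rulebook(coords, (3, 3, 3))
        expected = rulebook_pairs_bruteforce(coords, (3, 3, 3))
        for k, (in_idx, out_idx) in enumerate(rb.pairs):
            got = sorted(zip(in_idx.tolist(), out_idx.tolist()))
            assert got == expected[k]

    def test_inverse_requires_prior(self):
        with pytest.raises(ValueError):
            build_rulebook(np.array([[0, 0, 0]]), (2, 2, 2), 2, "inverse")

    def test_invalid_arguments(self):
        c = np.array([[0, 0, 0]])
        with pytest.raises(ValueError):
            build_rulebook(c, (3, 3, 3), 0, "strided")
        with pytest.raises(ValueError):
            build_rulebook(c, (2, 2, 2), 1, "submanifold")  # even kernel
        with pytest.raises(ValueError):
            build_rulebook(c, (3, 3, 3), 1, "nonsense")


# ---------------------------------------------------------------------------
# sparse_conv numerics
# ---------------------------------------------------------------------------

class TestSparseConv:
    def _params(self, kernel, c_in, c_out, rng):
        kv = int(np.prod(kernel))
        return ConvParams(
            weights=Tensor(rng.standard_normal((kv, c_in, c_out)),
                           requires_grad=True),
            bias=Tensor(rng.standard_normal(c_out), requires_grad=True),
        )

    def test_identity_kernel(self):
        rng = np.random.default_rng(3)
        coords = random_occupancy(rng)
        feats = rng.standard_normal((len(coords), 4))
        kv = 27
        w = np.zeros((kv, 4, 4))
        w[13] = np.eye(4)  # center offset
        rb = build_rulebook(coords, (3, 3, 3))
        out = sparse_conv(feats, rb, ConvParams(weights=Tensor(w)))
        np.testing.assert_allclose(out.data, feats)

    def test_zero_weights_bias_only(self):
        rng = np.random.default_rng(4)
        coords = random_occupancy(rng)
        b = np.array([1.0, -2.0])
        rb = build_rulebook(coords, (3, 3, 3))
        p = ConvParams(weights=Tensor(np.zeros((27, 3, 2))), bias=Tensor(b))
        out = sparse_conv(np.ones((len(coords), 3)), rb, p)
        np.testing.assert_allclose(out.data, np.tile(b, (len(coords), 1)))

    @pytest.mark.parametrize("kernel,mode,stride", [
        ((3, 3, 3), "submanifold", 1),
        ((3, 1, 3), "submanifold", 1),
        ((1, 3, 3), "submanifold", 1),
        ((2, 2, 2), "strided", 2),
    ])
    def test_matches_dense_oracle(self, kernel, mode, stride):
        rng = np.random.default_rng(hash((kernel, mode)) % 2**31)
        coords = random_occupancy(rng, dim=8, p=0.25)
        feats = rng.standard_normal((len(coords), 3))
        p = self._params(kernel, 3, 5, rng)
        rb = build_rulebook(coords, kernel, stride, mode)
        got = sparse_conv(feats, rb, p)
        oc, expected = dense_reference(coords, feats, p.weights.data,
                                       p.bias.data, kernel, mode, stride)
        assert np.array_equal(rb.out_coords, oc)
        np.testing.assert_allclose(got.data, expected, atol=1e-5)

    def test_linearity(self):
        rng = np.random.default_rng(6)
        coords = random_occupancy(rng)
        x = rng.standard_normal((len(coords), 3))
        y = rng.standard_normal((len(coords), 3))
        rb = build_rulebook(coords, (3, 3, 3))
        p = ConvParams(weights=Tensor(rng.standard_normal((27, 3, 2))))
        lhs = sparse_conv(2.0 * x + 3.0 * y, rb, p).data
        rhs = 2.0 * sparse_conv(x, rb, p).data + \
            3.0 * sparse_conv(y, rb, p).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_inverse_restores_input_sites(self):
        rng = np.random.default_rng(7)
        coords = random_occupancy(rng, dim=8, p=0.4)
        down = build_rulebook(coords, (2, 2, 2), 2, "strided")
        up = build_rulebook(coords, (2, 2, 2), 2, "inverse", prior=down)
        assert np.array_equal(up.out_coords, coords)
        # transposed linear map: <conv(x), y> == <x, conv_T(y)>
        p = ConvParams(weights=Tensor(rng.standard_normal((8, 3, 3))))
        x = rng.standard_normal((len(coords), 3))
        y = rng.standard_normal((len(down.out_coords), 3))
        fwd = sparse_conv(x, down, p).data
        pt = ConvParams(
            weights=Tensor(np.transpose(p.weights.data, (0, 2, 1)))
        )
        bwd = sparse_conv(y, up, pt).data
        np.testing.assert_allclose((fwd * y).sum(), (x * bwd).sum(),
                                   rtol=1e-10)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class TestAspcBlock:
    def _rulebooks(self, coords):
        return (build_rulebook(coords, (3, 1, 3)),
                build_rulebook(coords, (1, 3, 3)))

    def test_zero_weights_reduce_to_shortcut(self):
        rng = np.random.default_rng(8)
        coords = random_occupancy(rng)
        block = ASPCBlock(4, 4, init_rng(0))
        for conv in (block.conv_a1, block.conv_a2, block.conv_b1,
                     block.conv_b2):
            conv.params.weights.data[:] = 0.0
            conv.params.bias.data[:] = 0.0
        x = rng.standard_normal((len(coords), 4))
        rb_a, rb_b = self._rulebooks(coords)
        out = block(x, rb_a, rb_b)
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_site_set_unchanged(self):
        rng = np.random.default_rng(9)
        coords = random_occupancy(rng)
        rb_a, rb_b = self._rulebooks(coords)
        block = ASPCBlock(3, 6, init_rng(1))
        out = block(rng.standard_normal((len(coords), 3)), rb_a, rb_b)
        assert out.data.shape == (len(coords), 6)
        assert np.array_equal(rb_a.out_coords, coords)

    def test_gradient_matches_finite_differences(self):
        from test_autodiff import numeric_grad

        coords = np.array([[1, 1, 1], [1, 2, 1], [2, 1, 1], [3, 3, 3],
                           [1, 1, 2]])
        rb_a, rb_b = self._rulebooks(coords)
        block = ASPCBlock(2, 2, init_rng(2))
        w = np.random.default_rng(0).standard_normal((5, 2))
        x0 = np.random.default_rng(1).standard_normal((5, 2))

        def scalar(x):
            return (block(Tensor(x), rb_a, rb_b) * w).sum().item()

        t = Tensor(x0.copy(), requires_grad=True)
        (block(t, rb_a, rb_b) * w).sum().backward()
        np.testing.assert_allclose(t.grad, numeric_grad(scalar, x0.copy()),
                                   atol=1e-4)


class TestIspcBlock:
    def test_down_up_restores_coords(self):
        rng = np.random.default_rng(10)
        coords = random_occupancy(rng, dim=8, p=0.35)
        down = build_rulebook(coords, (2, 2, 2), 2, "strided")
        up = build_rulebook(coords, (2, 2, 2), 2, "inverse", prior=down)
        block = ISPCBlock(3, 4, 4, init_rng(3))
        coarse = rng.standard_normal((len(down.out_coords), 3))
        skip = rng.standard_normal((len(coords), 4))
        out = block(coarse, skip, up)
        assert out.data.shape == (len(coords), 4)

    def test_mismatched_skip_rejected(self):
        rng = np.random.default_rng(11)
        coords = random_occupancy(rng)
        down = build_rulebook(coords, (2, 2, 2), 2, "strided")
        up = build_rulebook(coords, (2, 2, 2), 2, "inverse", prior=down)
        block = ISPCBlock(3, 4, 4, init_rng(4))
        coarse = rng.standard_normal((len(down.out_coords), 3))
        bad_skip = rng.standard_normal((len(coords) + 1, 4))
        with pytest.raises(ValueError):
            block(coarse, bad_skip, up)

    def test_random_coords_set_equality(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            coords = random_occupancy(rng, dim=8, p=0.3)
            down = build_rulebook(coords, (2, 2, 2), 2, "strided")
            up = build_rulebook(coords, (2, 2, 2), 2, "inverse", prior=down)
            assert {tuple(c) for c in up.out_coords} == \
                {tuple(c) for c in coords}


class TestVoxelUNet:
    def test_single_voxel_passes_through(self):
        plan = build_unet_plan(np.array([[0, 0, 0]]), n_stages=2)
        net = VoxelUNet(3, [4, 8], init_rng(5))
        out, stages = net(np.ones((1, 3)), plan)
        assert out.data.shape == (1, 4)
        assert len(stages) == 2

    def test_stage_site_counts_non_increasing(self):
        rng = np.random.default_rng(12)
        coords = random_occupancy(rng, dim=8, p=0.5)
        plan = build_unet_plan(coords, n_stages=3)
        counts = [len(c) for c in plan.level_coords]
        assert counts == sorted(counts, reverse=True)

    def test_gradient_reaches_first_layer(self):
        rng = np.random.default_rng(13)
        coords = random_occupancy(rng, dim=8, p=0.4)
        plan = build_unet_plan(coords, n_stages=2)
        net = VoxelUNet(3, [4, 4], init_rng(6))
        x = Tensor(rng.standard_normal((len(coords), 3)))
        out, _ = net(x, plan)
        (out * out).sum().backward()
        first = net.aspc[0].conv_a1.params.weights
        assert first.grad is not None
        assert np.abs(first.grad).max() > 0

    def test_output_coords_full_resolution(self):
        rng = np.random.default_rng(14)
        coords = random_occupancy(rng, dim=8, p=0.4)
        plan = build_unet_plan(coords, n_stages=2)
        net = VoxelUNet(2, [4, 4], init_rng(7))
        out, _ = net(rng.standard_normal((len(coords), 2)), plan)
        assert out.data.shape[0] == len(coords)


class TestForwardGrid:
    def test_grid_in_grid_out(self):
        from ffnet3d.voxelgrid import GridSpec, SparseGrid

        rng = np.random.default_rng(15)
        coords = random_occupancy(rng, dim=8, p=0.4)
        plan = build_unet_plan(coords, n_stages=2)
        net = VoxelUNet(3, [4, 4], init_rng(8))
        spec = GridSpec(origin=np.zeros(3), voxel_size=np.ones(3),
                        dims=np.full(3, 8))
        grid = SparseGrid(coords=coords,
                          features=Tensor(rng.standard_normal((len(coords), 3))),
                          spec=spec)
        full, stages = net.forward_grid(grid, plan)
        assert np.array_equal(full.coords, coords)
        assert [g.level for g in stages] == [0, 1]
        assert np.allclose(stages[1].spec.voxel_size, 2.0)
        # a mismatched grid is rejected
        import pytest as _pytest
        bad = SparseGrid(coords=coords[:-1],
                         features=Tensor(np.zeros((len(coords) - 1, 3))),
                         spec=spec)
        with _pytest.raises(ValueError):
            net.forward_grid(bad, plan)
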