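"""Selective-kernel fusion and the three-branch generator."""

import numpy as np
import pytest

from cyclesk.generator import (ABLATIONS, Conv1x1Branch, GeneratorConfig,
                               RedCNNBranch, SKFusionParams, SKGenerator,
                               UNetBranch, branch_softmax, compact_feature,
                               global_avg_pool, sk_fuse)
from cyclesk.nn import Tensor


def _fmap(rng, c=6, h=8, w=8, n=1):
    return Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))


class TestBranches:
    def test_redcnn_shape_and_zero_preservation(self, rng):
        br = RedCNNBranch(16, 3, 3, rng)
        x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
        assert br(x).shape == (1, 16, 64, 64)
        zero = br(Tensor(np.zeros((1, 1, 16, 16), np.float32)))
        assert np.all(zero.data == 0.0)  # zero biases + ReLU(0)=0

    def test_unet_shape_and_bottleneck_arithmetic(self, rng):
        for depth in (2, 3):
            br = UNetBranch(8, depth, 4, rng)
            x = Tensor(rng.random((1, 1, 64, 64)).astype(np.float32))
            assert br(x).shape == (1, 8, 64, 64)
            assert br.effective_depth(64, 64) == depth  # 64 / 2^d >= 1

    def test_unet_depth_autoreduces_with_warning(self, rng):
        br = UNetBranch(4, 5, 4, rng)  # 2^5 = 32 does not divide 24
        x = Tensor(rng.random((1, 1, 24, 24)).astype(np.float32))
        with pytest.warns(UserWarning, match="depth reduced"):
            out = br(x)
        assert out.shape == (1, 4, 24, 24)

    def test_conv1x1_is_pointwise(self, rng):
        br = Conv1x1Branch(4, rng)
        x = rng.random((1, 1, 8, 8)).astype(np.float32)
        out = br(Tensor(x)).data
        xp = x.copy()
        xp[0, 0, 1, 2], xp[0, 0, 5, 5] = xp[0, 0, 5, 5], xp[0, 0, 1, 2]
        outp = br(Tensor(xp)).data
        expected = out.copy()
        expected[:, :, [1, 5], [2, 5]] = out[:, :, [5, 1], [5, 2]]
        np.testing.assert_allclose(outp, expected, atol=1e-6)

    def test_conv1x1_identity_weights_replicate_input(self, rng):
        br = Conv1x1Branch(1, rng)
        br.conv.weight.data[:] = 1.0
        br.conv.bias.data[:] = 0.0
        x = rng.random((1, 1, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(br(Tensor(x)).data[0, 0], x[0, 0],
                                   atol=1e-6)


class TestSKOps:
    def test_global_avg_pool_closed_form(self):
        u = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], np.float32))
        assert global_avg_pool(u).data[0, 0] == pytest.approx(2.5)
        const = Tensor(np.full((1, 3, 4, 4), 2.0, np.float32))
        np.testing.assert_allclose(global_avg_pool(const).data, 2.0)

    def test_global_avg_pool_linearity(self, rng):
        u1, u2 = _fmap(rng), _fmap(rng)
        np.testing.assert_allclose(
            global_avg_pool(u1 + u2).data,
            global_avg_pool(u1).data + global_avg_pool(u2).data, atol=1e-5)

    def test_compact_feature_shape_and_nonnegative(self, rng):
        params = SKFusionParams(6, 3, 3, rng)
        s = Tensor(rng.normal(size=(2, 6)).astype(np.float32))
        z = compact_feature(s, params)
        assert z.shape == (2, 3)
        assert np.all(z.data >= 0.0)

    def test_compact_feature_warns_when_not_compact(self, rng):
        with pytest.warns(UserWarning, match="not compact"):
            SKFusionParams(4, 4, 3, rng)

    def test_branch_softmax_symmetry_and_closed_form(self, rng):
        params = SKFusionParams(4, 2, 3, rng)
        # force equal logits: zero heads
        for h in params.heads:
            h.weight.data[:] = 0.0
        z = Tensor(rng.random((1, 2)).astype(np.float32))
        w = branch_softmax(z, params)
        for wi in w:
            np.testing.assert_allclose(wi.data, 1 / 3, atol=1e-6)
        # logits (ln 2, 0, 0) -> (0.5, 0.25, 0.25)
        params.heads[0].weight.data[:] = 0.0
        z1 = Tensor(np.ones((1, 2), np.float32))

        class FakeHead:
            def __init__(self, v):
                self.v = v

            def __call__(self, z):
                return Tensor(np.full((1, 4), self.v, np.float32))

        params.heads = [FakeHead(np.log(2.0)), FakeHead(0.0), FakeHead(0.0)]
        a, b, c = branch_softmax(z1, params)
        np.testing.assert_allclose(a.data, 0.5, atol=1e-6)
        np.testing.assert_allclose(b.data, 0.25, atol=1e-6)
        np.testing.assert_allclose(c.data, 0.25, atol=1e-6)

    def test_weights_sum_to_one_for_random_inputs(self, rng):
        params = SKFusionParams(8, 4, 3, rng)
        for _ in range(100):
            z = Tensor(rng.normal(size=(1, 4)).astype(np.float32))
            w = branch_softmax(z, params)
            total = sum(wi.data for wi in w)
            np.testing.assert_allclose(total, 1.0, atol=1e-6)
            for wi in w:
                assert np.all(wi.data > 0) and np.all(wi.data < 1)

    def test_fuse_degenerate_selection_returns_first_branch(self, rng):
        params = SKFusionParams(4, 2, 3, rng)

        class BigHead:
            def __call__(self, z):
                return Tensor(np.full((1, 4), 50.0, np.float32))

        class SmallHead:
            def __call__(self, z):
                return Tensor(np.full((1, 4), -50.0, np.float32))

        params.heads = [BigHead(), SmallHead(), SmallHead()]
        u1, u2, u3 = (_fmap(rng, c=4) for _ in range(3))
        v = sk_fuse([u1, u2, u3], params)
        np.testing.assert_allclose(v.data, u1.data, atol=1e-5)

    def test_fuse_equal_branches_is_identity(self, rng):
        params = SKFusionParams(4, 2, 3, rng)
        w = _fmap(rng, c=4)
        v = sk_fuse([w, Tensor(w.data.copy()), Tensor(w.data.copy())], params)
        np.testing.assert_allclose(v.data, w.data, atol=1e-5)

    def test_fuse_convex_combination_envelope(self, rng):
        params = SKFusionParams(6, 3, 3, rng)
        for _ in range(10):
            u = [_fmap(rng) for _ in range(3)]
            v = sk_fuse(u, params).data
            stack = np.stack([ui.data for ui in u])
            assert np.all(v >= stack.min(axis=0) - 1e-5)
            assert np.all(v <= stack.max(axis=0) + 1e-5)

    def test_fuse_shape_mismatch_names_branch(self, rng):
        params = SKFusionParams(4, 2, 3, rng)
        with pytest.raises(ValueError, match="branch 2"):
            sk_fuse([_fmap(rng, c=4), _fmap(rng, c=4, h=4), _fmap(rng, c=4)],
                    params)

    def test_fusion_state_descriptor_is_spatial_mean(self, rng):
        params = SKFusionParams(6, 3, 3, rng)
        u = [_fmap(rng) for _ in range(3)]
        _, state = sk_fuse(u, params, return_state=True)
        total = u[0].data + u[1].data + u[2].data
        np.testing.assert_allclose(state.S, total.mean(axis=(2, 3)),
                                   atol=1e-5)
        np.testing.assert_allclose(state.weights.sum(axis=1), 1.0, atol=1e-6)


class TestSKGenerator:
    def test_output_shape_matches_input(self, small_gen_cfg, rng):
        gen = SKGenerator(small_gen_cfg, seed=0)
        out = gen.generate(rng.random((64, 64)).astype(np.float32))
        assert out.shape == (64, 64)

    def test_fixed_seed_is_bit_deterministic(self, small_gen_cfg, rng):
        x = rng.random((32, 32)).astype(np.float32)
        a = SKGenerator(small_gen_cfg, seed=3).generate(x)
        b = SKGenerator(small_gen_cfg, seed=3).generate(x)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("ablation", ABLATIONS)
    def test_all_ablations_run_forward(self, ablation, rng):
        cfg = GeneratorConfig(channels=8, redcnn_layers=2, unet_layers=2,
                              reduction_dim=4, ablation=ablation)
        gen = SKGenerator(cfg, seed=1)
        out = gen.generate(rng.random((64, 64)).astype(np.float32))
        assert out.shape == (64, 64)
        assert np.isfinite(out).all()

    def test_redcnn_only_ignores_unet_parameters(self, rng):
        cfg = GeneratorConfig(channels=8, redcnn_layers=2, unet_layers=2,
                              reduction_dim=4, ablation="redcnn_only")
        gen = SKGenerator(cfg, seed=2)
        x = rng.random((32, 32)).astype(np.float32)
        base = gen.generate(x)
        assert gen.unet is None  # dead branch is not even constructed
        np.testing.assert_array_equal(base, gen.generate(x))

    def test_residual_mode_adds_input(self, rng):
        x = rng.random((32, 32)).astype(np.float32)
        plain = GeneratorConfig(channels=4, redcnn_layers=2, unet_layers=2,
                                reduction_dim=2)
        res = GeneratorConfig(channels=4, redcnn_layers=2, unet_layers=2,
                              reduction_dim=2, residual_output=True)
        out_p = SKGenerator(plain, seed=5).generate(x)
        out_r = SKGenerator(res, seed=5).generate(x)
        np.testing.assert_allclose(out_r, out_p + x, atol=1e-6)

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError, match="ablation"):
            GeneratorConfig(ablation="bogus")
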