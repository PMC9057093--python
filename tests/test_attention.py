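"""Residual-attention stage: branch algebra, shapes, differentiability."""

import numpy as np
import pytest

from fmriatt.attention import (
    AttentionBranch,
    AttentionModule,
    AttentionModuleSpec,
    ConfigurationError,
    ResBlock,
    ResBlockSpec,
    attention_combine,
)
from _utils import fd_gradcheck, randomize_params


def _zero_convs(module):
    for name, p in module.named_parameters():
        if "weight" in name or "bias" in name:
            p.data = np.zeros_like(p.data)


class TestResBlock:
    def test_identity_with_zero_weights_no_norm(self):
        rng = np.random.default_rng(0)
        rb = ResBlock(ResBlockSpec(3, 3, stride=1, normalize=False), rng=rng)
        _zero_convs(rb)
        x = rng.normal(size=(2, 5, 5, 5, 3)).astype(np.float32)
        np.testing.assert_array_equal(rb.forward(x), x)

    def test_stride_halves_grid(self):
        rng = np.random.default_rng(1)
        rb = ResBlock(ResBlockSpec(4, 6, stride=2), rng=rng)
        out = rb.forward(rng.normal(size=(1, 8, 8, 8, 4)).astype(np.float32))
        assert out.shape == (1, 4, 4, 4, 6)

    def test_matches_hand_composed_primitives(self):
        # compose the same primitive sequence manually and compare
        rng = np.random.default_rng(2)
        rb = ResBlock(ResBlockSpec(2, 3, stride=2), rng=rng).astype(np.float64)
        rb.eval()
        x = np.random.default_rng(3).normal(size=(2, 6, 6, 6, 2))
        expected = rb.conv2.forward(
            rb.act2.forward(rb.norm2.forward(
                rb.conv1.forward(rb.act1.forward(rb.norm1.forward(x)))
            ))
        ) + rb.proj.forward(x)
        np.testing.assert_allclose(rb.forward(x), expected, rtol=1e-12)

    def test_channel_mismatch_raises(self):
        rb = ResBlock(ResBlockSpec(2, 2))
        with pytest.raises(ValueError, match="channels"):
            rb.forward(np.zeros((1, 4, 4, 4, 3), dtype=np.float32))


class TestAttentionBranch:
    def test_mask_strictly_in_unit_interval(self):
        rng = np.random.default_rng(4)
        br = AttentionBranch(AttentionModuleSpec(2, 3, depth_steps=2), rng=rng)
        br.eval()
        a = br.forward(rng.normal(size=(2, 8, 8, 8, 2)).astype(np.float32))
        assert np.all(a > 0) and np.all(a < 1)

    def test_zero_logits_give_half(self):
        rng = np.random.default_rng(5)
        br = AttentionBranch(AttentionModuleSpec(2, 2, depth_steps=1), rng=rng)
        br.out_conv.weight.data[:] = 0
        br.out_conv.bias.data[:] = 0
        br.eval()
        a = br.forward(rng.normal(size=(1, 4, 4, 4, 2)).astype(np.float32))
        np.testing.assert_allclose(a, 0.5, rtol=1e-6)

    def test_u_shape_trace(self):
        # 16^3 input, two down-steps: bottleneck 4^3, output back at 16^3
        rng = np.random.default_rng(6)
        spec = AttentionModuleSpec(1, 2, depth_steps=2, main_stride=1)
        br = AttentionBranch(spec, rng=rng)
        br.eval()
        x = rng.normal(size=(1, 16, 16, 16, 1)).astype(np.float32)
        shapes = []
        h = x
        for pool, rb in zip(br.pools, br.down_blocks):
            h = rb(pool(h))
            shapes.append(h.shape[1:4])
        assert shapes[-1] == (4, 4, 4)
        assert br.forward(x).shape == (1, 16, 16, 16, 2)

    def test_strided_branch_lands_on_main_grid(self):
        rng = np.random.default_rng(7)
        spec = AttentionModuleSpec(2, 4, depth_steps=2, main_stride=2)
        mod = AttentionModule(spec, rng=rng)
        mod.eval()
        out, a = mod.forward(rng.normal(size=(1, 16, 16, 16, 2)).astype(np.float32))
        assert out.shape == (1, 8, 8, 8, 4) == a.shape

    def test_collapse_raises_configuration_error(self):
        rng = np.random.default_rng(8)
        br = AttentionBranch(AttentionModuleSpec(1, 1, depth_steps=3), rng=rng)
        with pytest.raises(ConfigurationError, match="collapses"):
            br.forward(np.zeros((1, 4, 4, 4, 1), dtype=np.float32))

    def test_strided_module_requires_a_down_step(self):
        with pytest.raises(ConfigurationError):
            AttentionModuleSpec(1, 1, depth_steps=0, main_stride=2)


class TestAttentionCombine:
    def test_zero_mask_is_identity(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(2, 4, 4, 4, 3))
        np.testing.assert_array_equal(attention_combine(m, np.zeros_like(m)), m)

    def test_zero_features_annihilate(self):
        a = np.random.default_rng(10).random((1, 4, 4, 4, 2))
        np.testing.assert_array_equal(
            attention_combine(np.zeros_like(a), a), 0.0
        )

    def test_bounded_amplification(self):
        rng = np.random.default_rng(11)
        m = rng.random((2, 4, 4, 4, 2)) + 0.1
        a = rng.random((2, 4, 4, 4, 2)) * 0.98 + 0.01
        out = attention_combine(m, a)
        assert np.all(out > m) and np.all(out < 2 * m)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            attention_combine(np.zeros((1, 2, 2, 2, 1)), np.zeros((1, 2, 2, 2, 2)))


class TestAttentionModule:
    def test_shape_contract(self):
        rng = np.random.default_rng(12)
        mod = AttentionModule(
            AttentionModuleSpec(4, 8, depth_steps=2, main_stride=2), rng=rng
        )
        mod.eval()
        out, mask = mod.forward(
            rng.normal(size=(3, 16, 16, 16, 4)).astype(np.float32)
        )
        assert out.shape == (3, 8, 8, 8, 8) and mask.shape == (3, 8, 8, 8, 8)

    def test_zero_branch_gives_1p5_times_main(self):
        rng = np.random.default_rng(13)
        mod = AttentionModule(AttentionModuleSpec(2, 3, depth_steps=1), rng=rng)
        mod.branch.out_conv.weight.data[:] = 0
        mod.branch.out_conv.bias.data[:] = 0
        mod.eval()
        x = rng.normal(size=(1, 6, 6, 6, 2)).astype(np.float32)
        out, mask = mod.forward(x)
        m = mod.main.forward(x)
        np.testing.assert_allclose(out, 1.5 * m, rtol=1e-5)

    def test_decomposes_into_independent_branches(self):
        rng = np.random.default_rng(14)
        mod = AttentionModule(
            AttentionModuleSpec(2, 4, depth_steps=1, main_stride=2), rng=rng
        )
        mod.eval()
        x = rng.normal(size=(2, 8, 8, 8, 2)).astype(np.float32)
        out, mask = mod.forward(x)
        m = mod.main.forward(x)
        a = mod.branch.forward(x)
        np.testing.assert_allclose(out, attention_combine(m, a), rtol=1e-5)
        np.testing.assert_allclose(mask, a, rtol=1e-6)

    def test_amplification_bounds_and_sign(self):
        rng = np.random.default_rng(15)
        mod = AttentionModule(AttentionModuleSpec(2, 2, depth_steps=1), rng=rng)
        mod.eval()
        out, mask = mod.forward(
            rng.normal(size=(2, 6, 6, 6, 2)).astype(np.float32)
        )
        m = mod._m
        assert np.all(np.abs(out) >= np.abs(m) - 1e-7)
        assert np.all(np.abs(out) <= 2 * np.abs(m) + 1e-7)
        nz = np.abs(m) > 1e-6
        assert np.all(np.sign(out[nz]) == np.sign(m[nz]))

    def test_mask_monotonically_scales_output(self):
        m = np.full((1, 2, 2, 2, 1), 2.0)
        a1 = np.full_like(m, 0.3)
        a2 = a1.copy()
        a2[0, 1, 1, 1, 0] = 0.6
        d = attention_combine(m, a2) - attention_combine(m, a1)
        assert d[0, 1, 1, 1, 0] > 0
        untouched = np.ones_like(d, dtype=bool)
        untouched[0, 1, 1, 1, 0] = False
        assert np.all(d[untouched] == 0)

    def test_finite_difference_gradients(self):
        rng = np.random.default_rng(16)
        mod = AttentionModule(
            AttentionModuleSpec(2, 3, depth_steps=1, main_stride=2), rng=rng
        ).astype(np.float64)
        randomize_params(mod, rng)
        mod.train()
        x = rng.normal(size=(2, 4, 4, 4, 2))
        assert fd_gradcheck(mod, x, seed=1) < 1e-3


class TestCombineProperty:
    def test_combine_bounds_hypothesis(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(seed=st.integers(0, 1000))
        def inner(seed):
            rng = np.random.default_rng(seed)
            m = rng.normal(size=(2, 3, 3, 3, 2))
            a = rng.uniform(1e-6, 1 - 1e-6, size=m.shape)
            out = attention_combine(m, a)
            assert np.all(np.abs(out) >= np.abs(m))
            assert np.all(np.abs(out) <= 2 * np.abs(m))
            nz = m != 0
            assert np.all(np.sign(out[nz]) == np.sign(m[nz]))

        inner()
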