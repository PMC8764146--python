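"""Unit and property tests for the cross-scale self-attention block."""

import numpy as np
import pytest

from msstgan.attention import (MsSTBlock, apply_attention, attention_oracle,
                               compute_attention, msst_forward, project_qkv)
from msstgan.nn import Tensor

TOL = 1e-5


def _block(c=8, stages=(4, 4, 4), r=8, seed=0):
    return MsSTBlock(c, stage_channels=stages, reduction=r,
                     rng=np.random.default_rng(seed))


class TestProjections:
    def test_channel_arithmetic(self, rng):
        blk = _block(c=8, r=8)
        f = rng.normal(size=(1, 8, 3, 3))
        q, k, v = project_qkv(f, f, blk)
        assert q.shape == (1, 1, 3, 3)
        assert k.shape == (1, 1, 3, 3)
        assert v.shape == (1, 8, 3, 3)

    def test_identity_projection_returns_input(self, rng):
        blk = _block(c=4, r=1)
        blk.q_proj.weight.data = np.eye(4).reshape(4, 4, 1, 1)
        blk.q_proj.bias.data[:] = 0.0
        f_a = rng.normal(size=(2, 4, 3, 3))
        q, _, _ = project_qkv(f_a, np.zeros_like(f_a), blk)
        np.testing.assert_allclose(q.data, f_a, atol=TOL)

    def test_projection_matches_per_position_matrix_product(self, rng):
        # 1x1 conv == per-pixel matrix product with the projection weights
        blk = _block(c=8, r=8, seed=3)
        f_a = rng.normal(size=(1, 8, 3, 3))
        f_t = rng.normal(size=(1, 8, 3, 3))
        q, _, _ = project_qkv(f_a, f_t, blk)
        w = blk.q_proj.weight.data.reshape(1, 8)
        b = blk.q_proj.bias.data
        for i in range(3):
            for j in range(3):
                expected = w @ f_a[0, :, i, j] + b
                np.testing.assert_allclose(q.data[0, :, i, j], expected, atol=TOL)

    def test_shape_mismatch_names_both_shapes(self, rng):
        blk = _block()
        with pytest.raises(ValueError, match=r"\(1, 8, 3, 3\).*\(1, 8, 4, 4\)"):
            project_qkv(rng.normal(size=(1, 8, 3, 3)),
                        rng.normal(size=(1, 8, 4, 4)), blk)


class TestAttentionMap:
    def test_constant_energy_gives_uniform_weights(self):
        att = compute_attention(np.zeros((1, 2, 2, 2)), np.zeros((1, 2, 2, 2)))
        np.testing.assert_allclose(att.data, 0.25, atol=TOL)

    def test_rows_sum_to_one_and_entries_in_unit_interval(self, rng):
        for _ in range(10):
            q = rng.normal(size=(2, 3, 3, 4)) * rng.uniform(0.1, 5)
            k = rng.normal(size=(2, 3, 3, 4))
            att = compute_attention(q, k).data
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=TOL)
            assert (att >= 0).all() and (att <= 1).all()

    def test_matches_explicit_double_loop(self, rng):
        q = rng.normal(size=(1, 2, 2, 2))
        k = rng.normal(size=(1, 2, 2, 2))
        att = compute_attention(q, k).data
        qf = q.reshape(2, 4)
        kf = k.reshape(2, 4)
        for i in range(4):
            energies = [qf[:, i] @ kf[:, j] for j in range(4)]
            expected = np.exp(energies) / np.exp(energies).sum()
            np.testing.assert_allclose(att[0, i], expected, atol=TOL)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="query"):
            compute_attention(rng.normal(size=(1, 2, 2, 2)),
                              rng.normal(size=(1, 2, 3, 3)))


class TestApplyAttention:
    def test_identity_attention_returns_values(self, rng):
        v = rng.normal(size=(2, 3, 2, 2))
        att = np.tile(np.eye(4), (2, 1, 1))
        np.testing.assert_allclose(apply_attention(v, att).data, v, atol=TOL)

    def test_uniform_attention_averages_values(self, rng):
        v = rng.normal(size=(1, 3, 2, 2))
        att = np.full((1, 4, 4), 0.25)
        out = apply_attention(v, att).data
        mean = v.mean(axis=(2, 3), keepdims=True)
        np.testing.assert_allclose(out, np.broadcast_to(mean, v.shape), atol=TOL)

    def test_matches_triple_loop(self, rng):
        v = rng.normal(size=(1, 3, 2, 2))
        att = rng.uniform(size=(1, 4, 4))
        att /= att.sum(axis=-1, keepdims=True)
        out = apply_attention(v, att).data
        vf = v.reshape(3, 4)
        for c in range(3):
            for i in range(4):
                expected = sum(att[0, i, j] * vf[c, j] for j in range(4))
                assert abs(out[0, c, i // 2, i % 2] - expected) < TOL

    def test_spatial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="incompatible"):
            apply_attention(rng.normal(size=(1, 3, 2, 2)), np.full((1, 9, 9), 1 / 9))


class TestMsSTForward:
    @staticmethod
    def _stage_maps(rng, c=8, top=4):
        f1 = rng.normal(size=(1, 4, top * 8, top * 8))
        f2 = rng.normal(size=(1, 4, top * 4, top * 4))
        f3 = rng.normal(size=(1, 4, top * 2, top * 2))
        f_t = rng.normal(size=(1, c, top, top))
        return f1, f2, f3, f_t

    def test_zero_gamma_is_exact_identity(self):
        # the residual scale is initialized at 0, so a fresh block must pass
        # the top-stage features through unchanged
        for seed in range(10):
            rng = np.random.default_rng(seed)
            blk = _block(seed=seed)
            f1, f2, f3, f_t = self._stage_maps(rng)
            out = msst_forward(f1, f2, f3, f_t, blk)
            assert np.abs(out.data - f_t).max() == 0.0

    def test_doubling_composition(self, rng):
        # gamma = 1 with identity attention and identity value projection
        # reduces the residual update to F_T itself: output 2 * F_T
        f_t = rng.normal(size=(1, 3, 2, 2))
        att = np.eye(4)[None]
        f_m = apply_attention(f_t, att)
        out = Tensor(f_t) + 1.0 * f_m
        np.testing.assert_allclose(out.data, 2 * f_t, atol=TOL)

    def test_matches_composition_of_suboperations(self, rng):
        blk = _block(seed=11)
        blk.gamma.data = np.asarray(0.7)
        f1, f2, f3, f_t = self._stage_maps(rng)
        out = msst_forward(f1, f2, f3, f_t, blk)
        from msstgan.nn import functional as F

        fused = sum((conv(F.bilinear_resize(Tensor(f), 4, 4)).data
                     for f, conv in zip((f1, f2, f3), blk.down)), np.zeros_like(f_t))
        q, k, v = project_qkv(fused, f_t, blk)
        att = compute_attention(q, k)
        expected = f_t + 0.7 * apply_attention(v, att).data
        np.testing.assert_allclose(out.data, expected, atol=TOL)

    def test_shape_conservation(self, rng):
        blk = _block(seed=2)
        blk.gamma.data = np.asarray(1.3)
        f1, f2, f3, f_t = self._stage_maps(rng)
        assert msst_forward(f1, f2, f3, f_t, blk).shape == f_t.shape

    def test_stage_smaller_than_top_rejected(self, rng):
        blk = _block()
        tiny = rng.normal(size=(1, 4, 2, 2))
        f_t = rng.normal(size=(1, 8, 4, 4))
        with pytest.raises(ValueError, match="downsample"):
            msst_forward(tiny, tiny, tiny, f_t, blk)

    def test_indivisible_channel_reduction_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MsSTBlock(10, reduction=8)


class TestOracle:
    def test_uniform_limit_broadcasts_spatial_mean(self, rng):
        v = rng.normal(size=(1, 3, 2, 2))
        out = attention_oracle(np.zeros((1, 2, 2, 2)), np.zeros((1, 2, 2, 2)), v)
        mean = v.mean(axis=(2, 3), keepdims=True)
        np.testing.assert_allclose(out, np.broadcast_to(mean, v.shape), atol=TOL)

    def test_single_position_attends_to_itself(self, rng):
        v = rng.normal(size=(2, 4, 1, 1))
        q = rng.normal(size=(2, 2, 1, 1))
        k = rng.normal(size=(2, 2, 1, 1))
        np.testing.assert_allclose(attention_oracle(q, k, v), v, atol=TOL)

    @pytest.mark.parametrize("seed", range(10))
    def test_fast_path_agrees_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        b, cr, c = rng.integers(1, 3), rng.integers(1, 5), rng.integers(1, 9)
        h = w = rng.integers(1, 5)
        q = rng.normal(size=(b, cr, h, w))
        k = rng.normal(size=(b, cr, h, w))
        v = rng.normal(size=(b, c, h, w))
        fast = apply_attention(v, compute_attention(q, k)).data
        assert np.abs(fast - attention_oracle(q, k, v)).max() < TOL


def test_permutation_equivariance(rng):
    """Consistently permuting spatial positions of q, k, v permutes the
    output identically (no positional encoding)."""
    b, cr, c, h, w = 1, 2, 3, 2, 2
    q = rng.normal(size=(b, cr, h, w))
    k = rng.normal(size=(b, cr, h, w))
    v = rng.normal(size=(b, c, h, w))
    perm = rng.permutation(h * w)

    def permute(x):
        flat = x.reshape(x.shape[0], x.shape[1], h * w)[:, :, perm]
        return flat.reshape(x.shape)

    base = apply_attention(v, compute_attention(q, k)).data
    permuted = apply_attention(permute(v), compute_attention(permute(q), permute(k))).data
    np.testing.assert_allclose(permute(base), permuted, atol=TOL)
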