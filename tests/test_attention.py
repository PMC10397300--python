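"""Attention operations against explicit-loop / coordinate-mapping oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnganext import autograd as ag
from burnganext.attention import (
    AttentionBlock,
    ResidualAttentionModule,
    apply_channel_attention,
    channel_attention,
    channel_shuffle,
    residual_attention_block,
    rotate_subgroup,
    shuffle_permutation,
    spatial_attention,
    spatial_descriptor,
)
from burnganext.autograd import Tensor
from burnganext.config import AttentionConfig
from burnganext.errors import ConfigurationError, InputError


def rotation_coordinate_oracle(x: np.ndarray, r: int) -> np.ndarray:
    """Map each (i, j) through the r*pi/2 rotation matrix about the center."""
    c, h, w = x.shape
    out = np.empty_like(x)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    cos = int(round(np.cos(r * np.pi / 2)))
    sin = int(round(np.sin(r * np.pi / 2)))
    for i in range(h):
        for j in range(w):
            # centered coordinates (row axis points down): rotate (u, v)
            u, v = i - cy, j - cx
            ui = cos * u - sin * v
            vj = sin * u + cos * v
            out[:, int(round(ui + cy)), int(round(vj + cx))] = x[:, i, j]
    return out


class TestChannelShuffle:
    def test_degenerate_grouping_is_identity(self, rng):
        x = rng.normal(size=(8, 3, 3))
        np.testing.assert_array_equal(channel_shuffle(x, 1, 1), x)
        np.testing.assert_array_equal(channel_shuffle(x, 1, 8), x)

    def test_explicit_transpose_example(self):
        x = np.arange(4)[:, None, None] * np.ones((1, 2, 2))
        out = channel_shuffle(x, 2, 2)
        np.testing.assert_array_equal(out[:, 0, 0], [0, 2, 1, 3])

    def test_inverse_shuffle(self, rng):
        x = rng.normal(size=(12, 2, 2))
        np.testing.assert_array_equal(channel_shuffle(channel_shuffle(x, 3, 4), 4, 3), x)

    def test_preserves_channel_multiset(self, rng):
        x = rng.normal(size=(8, 4, 4))
        out = channel_shuffle(x, 2, 4)
        assert sorted(map(tuple, out.reshape(8, -1))) == sorted(map(tuple, x.reshape(8, -1)))

    def test_divisibility_enforced(self):
        with pytest.raises(ConfigurationError):
            shuffle_permutation(10, 3, 4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(1, 3))
    def test_shuffle_group_properties(self, n, s, unit):
        """shuffle(N,S) is a permutation, undone by shuffle(S,N)."""
        c = n * s * unit
        x = np.arange(c * 4, dtype=float).reshape(c, 2, 2)
        out = channel_shuffle(x, n, s)
        assert sorted(map(tuple, out.reshape(c, -1))) == sorted(map(tuple, x.reshape(c, -1)))
        np.testing.assert_array_equal(channel_shuffle(out, s, n), x)


class TestRotateSubgroup:
    def test_zero_rotation_identity(self, rng):
        x = rng.normal(size=(2, 3, 3))
        np.testing.assert_array_equal(rotate_subgroup(x, 0), x)

    def test_quarter_turn_2x2(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # [[a, b], [c, d]]
        np.testing.assert_array_equal(
            rotate_subgroup(x, 1), np.array([[[2.0, 4.0], [1.0, 3.0]]])
        )

    def test_full_turn_periodicity(self, rng):
        x = rng.normal(size=(3, 4, 4))
        y = x
        for _ in range(4):
            y = rotate_subgroup(y, 1)
        np.testing.assert_array_equal(y, x)

    def test_half_turn_composition(self, rng):
        x = rng.normal(size=(2, 5, 5))
        np.testing.assert_array_equal(
            rotate_subgroup(x, 2), rotate_subgroup(rotate_subgroup(x, 1), 1)
        )

    @pytest.mark.parametrize("r", [0, 1, 2, 3])
    def test_coordinate_mapping_oracle(self, rng, r):
        for size in (2, 3, 5):
            x = rng.normal(size=(2, size, size))
            np.testing.assert_allclose(
                rotate_subgroup(x, r), rotation_coordinate_oracle(x, r), atol=0
            )

    def test_preserves_value_multiset(self, rng):
        x = rng.normal(size=(2, 4, 4))
        assert sorted(rotate_subgroup(x, 3).ravel()) == sorted(x.ravel())

    def test_non_square_rejected(self, rng):
        with pytest.raises(InputError):
            rotate_subgroup(rng.normal(size=(2, 3, 4)), 1)


class TestResidualAttention:
    def test_hand_evaluated_constant_input(self):
        # one channel per subgroup, 2x2 maps, unit center 3x3 kernel: K = id
        cfg = AttentionConfig(groups=1, subgroups=4)
        kernel = np.zeros((1, 1, 3, 3))
        kernel[0, 0, 1, 1] = 1.0
        x = np.ones((4, 2, 2)) * np.array([1.0, 2.0, 3.0, 4.0])[:, None, None]
        out = residual_attention_block(x, kernel, cfg)
        # y0 = 1; y_s = s+1 multiplied by y0 = s+1
        np.testing.assert_allclose(out[0], 1.0)
        np.testing.assert_allclose(out[1], 2.0)
        np.testing.assert_allclose(out[2], 3.0)
        np.testing.assert_allclose(out[3], 4.0)

    def test_zero_gate_annihilates(self, rng):
        cfg = AttentionConfig(groups=1, subgroups=4)
        kernel = rng.normal(size=(1, 1, 3, 3))
        x = rng.normal(size=(4, 4, 4))
        x[0] = 0.0  # y0 = K(0) = 0
        out = residual_attention_block(x, kernel, cfg)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_subgroup_reduces_to_conv(self, rng):
        cfg = AttentionConfig(groups=1, subgroups=1)
        kernel = rng.normal(size=(2, 2, 3, 3))
        x = rng.normal(size=(2, 4, 4))
        out = residual_attention_block(x, kernel, cfg)
        ref = residual_attention_block(np.concatenate([x, x * 0]), kernel,
                                       AttentionConfig(groups=1, subgroups=2))[:2]
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_layer_matches_functional(self, rng):
        mod = ResidualAttentionModule(8, 4, np.random.default_rng(0))
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float64)
        out = mod.forward(Tensor(x), n_groups=1).data
        for b in range(2):
            ref = residual_attention_block(
                x[b], mod.kernel.weight.data.astype(np.float64),
                AttentionConfig(groups=1, subgroups=4),
            )
            np.testing.assert_allclose(out[b], ref, atol=1e-5)

    def test_subgroup_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            residual_attention_block(
                rng.normal(size=(6, 3, 3)), np.zeros((1, 1, 3, 3)),
                AttentionConfig(groups=1, subgroups=4),
            )


def channel_attention_loop_oracle(g, w1, b1, w2, b2):
    cg = g.shape[0]
    gap = np.array([g[c].mean() for c in range(cg)])
    h = np.array([max(0.0, gap @ w1[:, j] + b1[j]) for j in range(w1.shape[1])])
    z = np.array([h @ w2[:, c] + b2[c] for c in range(cg)])
    return 1.0 / (1.0 + np.exp(-z))


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        g = rng.normal(size=(4, 3, 3))
        out = channel_attention(g, np.zeros((4, 2)), np.zeros(2), np.zeros((2, 4)), np.zeros(4))
        np.testing.assert_allclose(out, 0.5)

    def test_spatial_permutation_invariance(self, rng):
        g = rng.normal(size=(4, 3, 3))
        w1, b1 = rng.normal(size=(4, 2)), rng.normal(size=2)
        w2, b2 = rng.normal(size=(2, 4)), rng.normal(size=4)
        perm = rng.permutation(9)
        gp = g.reshape(4, -1)[:, perm].reshape(4, 3, 3)
        np.testing.assert_allclose(
            channel_attention(g, w1, b1, w2, b2), channel_attention(gp, w1, b1, w2, b2),
            atol=1e-12,
        )

    def test_loop_oracle(self, rng):
        for _ in range(20):
            g = rng.normal(size=(4, 3, 3))
            w1, b1 = rng.normal(size=(4, 2)), rng.normal(size=2)
            w2, b2 = rng.normal(size=(2, 4)), rng.normal(size=4)
            np.testing.assert_allclose(
                channel_attention(g, w1, b1, w2, b2),
                channel_attention_loop_oracle(g, w1, b1, w2, b2),
                atol=1e-6,
            )

    def test_open_unit_interval(self, rng):
        g = rng.normal(size=(6, 2, 2)) * 10
        out = channel_attention(
            g, rng.normal(size=(6, 3)), rng.normal(size=3),
            rng.normal(size=(3, 6)), rng.normal(size=6),
        )
        assert ((out > 0) & (out < 1)).all()


class TestApplyChannelAttention:
    def test_single_group(self, rng):
        g = rng.normal(size=(4, 3, 3))
        m = rng.uniform(0.1, 0.9, size=4)
        np.testing.assert_allclose(
            apply_channel_attention([g], [m]), m[:, None, None] * g, atol=1e-12
        )

    def test_unit_weights_sum_groups(self, rng):
        gs = [rng.normal(size=(3, 2, 2)) for _ in range(3)]
        out = apply_channel_attention(gs, [np.ones(3)] * 3)
        np.testing.assert_allclose(out, sum(gs), atol=1e-12)

    def test_loop_oracle(self, rng):
        gs = [rng.normal(size=(4, 3, 3)) for _ in range(2)]
        ms = [rng.uniform(size=4) for _ in range(2)]
        expected = np.zeros((4, 3, 3))
        for n in range(2):
            for c in range(4):
                expected[c] += ms[n][c] * gs[n][c]
        np.testing.assert_allclose(apply_channel_attention(gs, ms), expected, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            apply_channel_attention([rng.normal(size=(4, 2, 2))], [np.ones(3)])


def spatial_attention_loop_oracle(c, w, variant="concat"):
    cc, h, wd = c.shape
    avg = np.array([[c[:, u, v].mean() for v in range(wd)] for u in range(h)])
    mx = np.array([[c[:, u, v].max() for v in range(wd)] for u in range(h)])
    sc = np.stack([avg, mx]) if variant == "concat" else (avg + mx)[None]
    pad = np.pad(sc, ((0, 0), (1, 1), (1, 1)))
    logits = np.zeros((h, wd))
    for u in range(h):
        for v in range(wd):
            for ci in range(sc.shape[0]):
                for du in range(3):
                    for dv in range(3):
                        logits[u, v] += w[0, ci, du, dv] * pad[ci, u + du, v + dv]
    gate = 1.0 / (1.0 + np.exp(-logits))
    return gate[None] * c


class TestSpatialAttention:
    def test_constant_input_descriptors_coincide(self):
        c = np.full((3, 4, 4), 1.7)
        sc = spatial_descriptor(c)
        np.testing.assert_allclose(sc[0], 1.7)
        np.testing.assert_allclose(sc[1], 1.7)

    def test_max_map_dominates_average(self, rng):
        sc = spatial_descriptor(rng.normal(size=(5, 4, 4)))
        assert (sc[1] >= sc[0] - 1e-12).all()

    def test_contraction_in_max_norm(self, rng):
        c = rng.normal(size=(8, 5, 5))
        out = spatial_attention(c, rng.normal(size=(1, 2, 3, 3)))
        assert (np.abs(out) <= np.abs(c) + 1e-12).all()
        assert np.abs(out).max() <= np.abs(c).max() + 1e-12

    def test_loop_oracle(self, rng):
        for variant in ("concat", "sum"):
            in_ch = 2 if variant == "concat" else 1
            for _ in range(10):
                c = rng.normal(size=(8, 5, 5))
                w = rng.normal(size=(1, in_ch, 3, 3))
                np.testing.assert_allclose(
                    spatial_attention(c, w, variant),
                    spatial_attention_loop_oracle(c, w, variant),
                    atol=1e-6,
                )


class TestAttentionBlock:
    def test_preserves_shape_and_differentiability(self, rng):
        blk = AttentionBlock(16, AttentionConfig(groups=2, subgroups=4, reduction=4),
                             np.random.default_rng(3))
        x = Tensor(rng.normal(size=(2, 16, 5, 5)).astype(np.float32), requires_grad=True)
        out = blk(x)
        assert out.shape == (2, 16, 5, 5)
        loss = ag.mean(out, (0, 1, 2, 3))
        ag.backward(loss)
        assert x.grad is not None and np.isfinite(x.grad).all()
        for p in blk.parameters():
            assert p.grad is None or np.isfinite(p.grad).all()

    def test_width_must_divide(self):
        with pytest.raises(ConfigurationError):
            AttentionBlock(10, AttentionConfig(groups=4, subgroups=4), np.random.default_rng(0))
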