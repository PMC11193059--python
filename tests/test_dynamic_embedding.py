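"""Dynamic word-embedding layer: lookup, multi-scale convolution, highway
gating, projection and pocket fusion."""

import numpy as np
import pytest

from seqdta.autodiff import Parameter, Tensor
from seqdta.config import DynamicEmbeddingConfig
from seqdta.dynamic_embedding import (DynamicWordEmbedding, Embedding, Highway,
                                      MultiScaleConv, Projection, fuse_pocket)

CFG = DynamicEmbeddingConfig(embed_dim=8, kernel_sizes=(1, 3, 5, 7),
                             filter_counts=(2, 2, 4, 8))


@pytest.fixture
def conv(rng):
    return MultiScaleConv(CFG, rng)


class TestEmbedding:
    def test_padding_index_embeds_to_zero(self, rng):
        emb = Embedding(5, 4, rng)
        out = emb(np.zeros((2, 6), dtype=int))
        assert not out.data.any()

    def test_deterministic_and_shape(self, rng):
        emb = Embedding(21, 8, rng)
        idx = np.array([[3, 1, 0, 4]])
        a, b = emb(idx), emb(idx)
        assert a.shape == (1, 4, 8)
        np.testing.assert_array_equal(a.data, b.data)

    def test_out_of_vocabulary_index_is_hard_error(self, rng):
        emb = Embedding(5, 4, rng)
        with pytest.raises(ValueError):
            emb(np.array([[5]]))

    def test_padding_row_gradient_frozen(self, rng):
        emb = Embedding(5, 4, rng)
        out = emb(np.array([[0, 1, 2]]))
        out.sum().backward()
        emb.freeze_padding()
        assert not emb.weight.grad[0].any()
        assert emb.weight.grad[1].any()


class TestMultiScaleConv:
    def test_output_width_is_sum_of_filter_counts(self, conv, rng):
        x = Tensor(rng.normal(size=(10, 8)))
        assert conv(x).shape == (10, 16)
        assert CFG.hidden_dim == 16

    def test_full_scale_hidden_dim_is_256(self):
        assert DynamicEmbeddingConfig().hidden_dim == 256 == 32 + 32 + 64 + 128

    def test_channel_blocks_equal_standalone_convolutions(self, conv, rng):
        """Slicing the concatenated output recovers each kernel's block."""
        x = Tensor(rng.normal(size=(9, 8)))
        out = conv(x).data
        offset = 0
        for k, w, b, c in zip(CFG.kernel_sizes, conv.weights, conv.biases,
                              CFG.filter_counts):
            block = MultiScaleConv._windows(x, k) @ w + b
            np.testing.assert_allclose(out[:, offset:offset + c], block.data)
            offset += c

    def test_kernel1_block_depends_on_own_row_only(self, conv, rng):
        x = rng.normal(size=(7, 8))
        zeroed = np.zeros_like(x)
        zeroed[3] = x[3]
        full = conv(Tensor(x)).data
        sparse = conv(Tensor(zeroed)).data
        np.testing.assert_allclose(full[3, :2], sparse[3, :2])

    def test_kernel7_receptive_field_is_three_neighbours(self, conv, rng):
        x = rng.normal(size=(12, 8))
        perturbed = x.copy()
        perturbed[6] += 1.0
        d = np.abs(conv(Tensor(x)).data - conv(Tensor(perturbed)).data)
        changed = np.nonzero(d[:, 8:16].sum(axis=1))[0]  # kernel-7 block
        assert changed.min() >= 3 and changed.max() <= 9

    def test_short_sequence_still_valid(self, conv, rng):
        x = Tensor(rng.normal(size=(2, 8)))  # shorter than the largest kernel
        assert conv(x).shape == (2, 16)

    def test_wrong_input_width_rejected(self, conv, rng):
        with pytest.raises(ValueError):
            conv(Tensor(rng.normal(size=(5, 7))))


class TestHighway:
    def test_gate_one_gives_identity(self, rng):
        hw = Highway(4, rng)
        hw.bg.data[:] = 50.0  # sigmoid -> 1
        x = rng.normal(size=(6, 4))
        np.testing.assert_allclose(hw(Tensor(x)).data, x, atol=1e-12)

    def test_gate_zero_gives_transform_branch(self, rng):
        hw = Highway(4, rng)
        hw.bg.data[:] = -50.0  # sigmoid -> 0
        x = rng.normal(size=(6, 4))
        expected = np.maximum(x @ hw.W.data + hw.b.data, 0.0)
        np.testing.assert_allclose(hw(Tensor(x)).data, expected, atol=1e-12)

    def test_hand_computed_two_unit_case(self, rng):
        """ft=[1,-1], W=I, b=0, Wg=0, bg=0 -> g=[.5,.5], out=[1.0,-0.5]."""
        hw = Highway(2, rng)
        hw.W.data = np.eye(2)
        hw.b.data[:] = 0.0
        hw.Wg.data[:] = 0.0
        hw.bg.data[:] = 0.0
        out = hw(Tensor(np.array([[1.0, -1.0]])))
        np.testing.assert_allclose(out.data, [[1.0, -0.5]])

    def test_jacobian_is_identity_at_gate_one(self, rng):
        hw = Highway(3, rng)
        hw.bg.data[:] = 60.0
        x = Parameter(rng.normal(size=(1, 3)))
        for j in range(3):
            x.grad = None
            hw(x)[0, j].backward()
            expected = np.zeros(3)
            expected[j] = 1.0
            np.testing.assert_allclose(x.grad[0], expected, atol=1e-12)


class TestProjectionAndPipeline:
    def test_projection_shape_and_bias_only_on_zero_input(self, rng):
        proj = Projection(16, 8, rng)
        proj.b.data[:] = np.arange(8.0)
        out = proj(Tensor(np.zeros((5, 16))))
        assert out.shape == (5, 8)
        np.testing.assert_allclose(out.data, np.tile(np.arange(8.0), (5, 1)))

    def test_all_padding_sequence_gives_constant_rows(self, rng):
        dwe = DynamicWordEmbedding(21, CFG, rng)
        for b in dwe.conv.biases:  # nonzero biases make the check non-trivial
            b.data[:] = rng.normal(size=b.shape)
        out = dwe(np.zeros((1, 10), dtype=int)).data[0]
        # away from edges, same-padded convolution of a constant input is
        # translation invariant -> identical rows
        interior = out[3:-3]
        np.testing.assert_allclose(interior, np.tile(interior[0], (len(interior), 1)))

    def test_end_to_end_shape_law(self, rng):
        dwe = DynamicWordEmbedding(21, CFG, rng)
        out = dwe(np.ones((2, 30), dtype=int))
        assert out.shape == (2, 30, CFG.embed_dim)

    def test_static_variant_skips_convolution(self, rng):
        dwe = DynamicWordEmbedding(21, CFG, rng, static=True)
        idx = np.array([[1, 2, 3]])
        np.testing.assert_array_equal(dwe(idx).data, dwe.embedding(idx).data)


class TestFusePocket:
    def test_zero_pocket_is_identity(self, rng):
        p = Tensor(rng.normal(size=(4, 8)))
        np.testing.assert_array_equal(fuse_pocket(p, Tensor(np.zeros((4, 8)))).data,
                                      p.data)

    def test_commutative(self, rng):
        a, b = Tensor(rng.normal(size=(4, 8))), Tensor(rng.normal(size=(4, 8)))
        np.testing.assert_array_equal(fuse_pocket(a, b).data, fuse_pocket(b, a).data)

    def test_full_pocket_doubles_protein_features(self, rng):
        """A pocket covering the whole protein re-uses the shared embedding
        weights, so fused features are exactly twice the protein features."""
        dwe = DynamicWordEmbedding(21, CFG, rng)
        idx = np.array([[5, 2, 9, 1]])
        vec = dwe(idx)
        np.testing.assert_allclose(fuse_pocket(vec, dwe(idx)).data, 2 * vec.data)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_pocket(Tensor(np.zeros((3, 8))), Tensor(np.zeros((4, 8))))
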