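"""Learnable density-map generator: shapes, masking, conservation."""

import numpy as np
import pytest

from densecount.autodiff import Tensor
from densecount.dmg_classical import fdm_density, gaussian_kernel
from densecount.io import PointSet
from densecount.ldm_generator import (
    KernelGenerator,
    SwinBlock,
    SwinConfig,
    generate_kernel_map,
    ldm_ground_truth,
    stamp_kernel_map,
)

TINY = SwinConfig(embed_dim=24, window=4, depths=(1, 1, 1), heads=(3, 6, 6), kernel_k=5)


@pytest.fixture(scope="module")
def tiny_generator():
    return KernelGenerator(TINY, rng=np.random.default_rng(0))


def random_image(rng, side=64):
    return rng.random((side, side, 3))


class TestSwinBlock:
    def test_identity_with_zero_projections(self):
        block = SwinBlock(8, 2, 4, shift=False, rng=np.random.default_rng(0))
        block.attn.proj.weight.data[:] = 0.0
        block.fc2.weight.data[:] = 0.0
        x = Tensor(np.random.default_rng(1).normal(size=(1, 8, 8, 8)))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-12)

    def test_shape_preserved_with_and_without_shift(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.normal(size=(2, 16, 16, 8)))
        for shift in (False, True):
            block = SwinBlock(8, 2, 4, shift=shift, rng=rng)
            assert block(x).shape == (2, 16, 16, 8)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        block = SwinBlock(8, 2, 4, shift=True, rng=rng)
        block(Tensor(rng.normal(size=(1, 8, 8, 8))))
        rows = block.attn.last_attention.sum(axis=-1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-5)

    def test_shifted_window_mask_zeroes_cross_window_pairs(self):
        rng = np.random.default_rng(4)
        block = SwinBlock(8, 2, 4, shift=True, rng=rng)
        block(Tensor(rng.normal(size=(1, 8, 8, 8))))
        from densecount.ldm_generator import _shift_mask

        mask = _shift_mask(8, 8, 4, 2)
        attn = block.attn.last_attention  # (nw, heads, T, T)
        blocked = np.broadcast_to(mask[:, None], attn.shape)
        assert np.all(attn[np.isneginf(blocked)] == 0.0)

    def test_window_larger_than_padded_side_errors(self):
        block = SwinBlock(8, 2, 16, shift=False, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            block(Tensor(np.zeros((1, 4, 4, 8))))


class TestKernelGeneratorShapes:
    @pytest.mark.parametrize("side", [64, 104, 640])
    def test_output_stride_is_8(self, side, tiny_generator):
        image = np.random.default_rng(side).random((side, side, 3))
        kmap = generate_kernel_map(tiny_generator, image)
        expected = -(-side // 8)
        assert kmap.shape == (expected, expected, TINY.kernel_k**2)

    def test_default_config_640(self):
        model = KernelGenerator(SwinConfig(), rng=np.random.default_rng(0))
        kmap = generate_kernel_map(model, np.zeros((64, 64, 3)))
        assert kmap.shape == (8, 8, 49)

    def test_deterministic_given_weights(self, tiny_generator):
        image = random_image(np.random.default_rng(5))
        a = generate_kernel_map(tiny_generator, image)
        b = generate_kernel_map(tiny_generator, image)
        np.testing.assert_array_equal(a, b)

    def test_constant_image_gives_constant_kernel_map(self, tiny_generator):
        image = np.full((64, 64, 3), 0.5)
        kmap = generate_kernel_map(tiny_generator, image)
        spatial_std = kmap.reshape(-1, kmap.shape[-1]).std(axis=0)
        assert spatial_std.max() < 1e-3

    def test_non_rgb_rejected(self, tiny_generator):
        with pytest.raises(ValueError):
            generate_kernel_map(tiny_generator, np.zeros((64, 64)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SwinConfig(patch_size=2)
        with pytest.raises(ValueError):
            SwinConfig(kernel_k=4)
        with pytest.raises(ValueError):
            SwinConfig(embed_dim=50, heads=(3, 6, 6))


class TestLdmGroundTruth:
    def test_count_conservation_random_weights(self, tiny_generator):
        rng = np.random.default_rng(6)
        image = random_image(rng, 64)
        points = PointSet(rng.uniform(0, 64, size=(37, 2)), 64, 64)
        dmap = ldm_ground_truth(tiny_generator, image, points)
        assert dmap.count == pytest.approx(37, abs=1e-4)
        assert dmap.stride == 8

    def test_zero_points_zero_map(self, tiny_generator):
        dmap = ldm_ground_truth(
            tiny_generator, np.zeros((64, 64, 3)), PointSet(np.zeros((0, 2)), 64, 64)
        )
        assert dmap.count == 0.0

    def test_head_forced_to_gaussian_matches_fdm(self, tiny_generator):
        """Generator emitting the FDM Gaussian vector everywhere == fdm_density."""
        gauss = gaussian_kernel(TINY.kernel_k / 4.0, TINY.kernel_k).values.ravel()
        forced = KernelGenerator(TINY, rng=np.random.default_rng(0))
        forced.load_state_dict(tiny_generator.state_dict())
        forced.head.weight.data[:] = 0.0
        forced.head.bias.data[:] = gauss
        rng = np.random.default_rng(7)
        image = random_image(rng, 64)
        points = PointSet(rng.uniform(0, 64, size=(20, 2)), 64, 64)
        ldm = ldm_ground_truth(forced, image, points)
        fdm = fdm_density(points, grid_shape=(8, 8), stride=8, kernel_size=TINY.kernel_k)
        np.testing.assert_allclose(ldm.values, fdm.values, atol=1e-5)


class TestDifferentiableStamping:
    def test_matches_numpy_path(self, tiny_generator):
        rng = np.random.default_rng(8)
        image = random_image(rng, 64)
        points = PointSet(rng.uniform(0, 64, size=(15, 2)), 64, 64)
        kmap = generate_kernel_map(tiny_generator, image)
        tensor_map = stamp_kernel_map(Tensor(kmap), points)
        numpy_map = ldm_ground_truth(tiny_generator, image, points)
        np.testing.assert_allclose(tensor_map.data, numpy_map.values, atol=1e-10)

    def test_gradient_reaches_generator(self, tiny_generator):
        rng = np.random.default_rng(9)
        image = random_image(rng, 32)
        points = PointSet(rng.uniform(0, 32, size=(6, 2)), 32, 32)
        tiny_generator.zero_grad()
        padded = image[None]
        kmap = tiny_generator(Tensor(padded))[0]
        gt = stamp_kernel_map(kmap, points)
        # any non-degenerate functional of the map
        loss = (gt * gt).sum()
        loss.backward()
        norms = [np.abs(p.grad).max() for p in tiny_generator.parameters() if p.grad is not None]
        assert norms and max(norms) > 0

    def test_conservation_under_stamping(self, tiny_generator):
        rng = np.random.default_rng(10)
        kmap = Tensor(rng.normal(size=(8, 8, 25)))  # includes negative entries
        points = PointSet(rng.uniform(0, 64, size=(12, 2)), 64, 64)
        stamped = stamp_kernel_map(kmap, points)
        assert stamped.data.sum() == pytest.approx(12, abs=1e-4)
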