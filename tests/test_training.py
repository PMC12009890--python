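"""Joint loss identities, augmentation, and a scaled-down joint training run."""

import numpy as np
import pytest

from densecount.io import PointSet
from densecount.ldm_generator import KernelGenerator
from densecount.mfen import MFEN
from densecount.synthetic_data import SceneSpec, render_scene, sample_points
from densecount.training import (
    TrainConfig,
    augment,
    cosine_similarity,
    default_tiny_configs,
    joint_loss,
    train_joint,
)


class TestCosineSimilarity:
    def test_identical_maps_give_one(self):
        a = np.random.default_rng(0).random((8, 8))
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 1.0
        b[3, 3] = 1.0
        assert cosine_similarity(a, b) == 0.0

    def test_zero_vector_guard(self):
        a = np.zeros((4, 4))
        b = np.ones((4, 4))
        assert cosine_similarity(a, b) == 0.0  # dot/zeta = 0, well defined


class TestJointLoss:
    def test_zero_iff_equal(self):
        maps = [np.random.default_rng(i).random((6, 6)) for i in range(3)]
        total, value = joint_loss(maps, [m.copy() for m in maps], lam=1.0)
        assert value.total == pytest.approx(0.0, abs=1e-12)
        perturbed = [m + 0.1 for m in maps]
        _, value2 = joint_loss(perturbed, maps, lam=1.0)
        assert value2.total > 0

    def test_orthogonal_unit_maps(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 1.0  # squared norm 1
        b[3, 3] = 1.0
        for lam in (0.5, 1.0, 2.0):
            _, value = joint_loss([a], [b], lam=lam)
            assert value.l2_term == pytest.approx(2.0)
            assert value.cosine_term == pytest.approx(1.0)
            assert value.total == pytest.approx(2.0 + lam)

    def test_lambda_linearity(self):
        rng = np.random.default_rng(1)
        est = [rng.random((5, 5)) for _ in range(2)]
        gt = [rng.random((5, 5)) for _ in range(2)]
        _, v1 = joint_loss(est, gt, lam=1.0)
        _, v2 = joint_loss(est, gt, lam=2.0)
        assert v2.total - v1.total == pytest.approx(v1.cosine_term)
        assert v1.total == pytest.approx(v1.l2_term + 1.0 * v1.cosine_term)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_loss([np.zeros((4, 4))], [np.zeros((5, 5))])


class TestAugment:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.image = rng.random((64, 64, 3))
        self.points = PointSet(rng.uniform(0, 63, size=(20, 2)), 64, 64)

    def test_double_hflip_is_identity(self):
        config = TrainConfig(hflip=True, brightness=False, gaussian_noise=False)
        rng = np.random.default_rng(1)
        img, pts = self.image, self.points
        flips = 0
        for _ in range(8):  # run until two flips have fired
            img2, pts2 = augment(img, pts, config, rng)
            if not np.array_equal(img2, img):
                flips += 1
            img, pts = img2, pts2
            if flips == 2:
                break
        assert flips == 2
        np.testing.assert_allclose(pts.points, self.points.points)
        np.testing.assert_allclose(img, self.image)

    def test_count_preserved_under_any_chain(self):
        config = TrainConfig()
        rng = np.random.default_rng(2)
        for _ in range(10):
            img, pts = augment(self.image, self.points, config, rng)
            assert pts.count == self.points.count
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_deterministic_given_seed(self):
        config = TrainConfig()
        a = augment(self.image, self.points, config, np.random.default_rng(3))
        b = augment(self.image, self.points, config, np.random.default_rng(3))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1].points, b[1].points)


def make_scenes(n, size=128, seed0=0):
    data = []
    for i in range(n):
        spec = SceneSpec(size=size, count_bin=(13, 68), seed=seed0 + i)
        rng = np.random.default_rng(seed0 + i)
        points = sample_points(spec, rng=rng)
        image = render_scene(points, spec, rng=rng)
        data.append((image, points))
    return data


class TestJointTraining:
    def test_smoke_loss_decreases_and_gradients_flow(self):
        """Scaled-down joint run: loss drops, GT integrals stay exact,
        generator receives gradient."""
        swin_cfg, mfen_cfg = default_tiny_configs()
        rng = np.random.default_rng(0)
        generator = KernelGenerator(swin_cfg, rng=rng)
        counter = MFEN(mfen_cfg, rng=rng)
        data = make_scenes(4, size=96)
        config = TrainConfig(seed=0, batch_size=2, hflip=True, brightness=True, gaussian_noise=True)
        log = train_joint(data, generator, counter, config, steps=10, lr=1e-4)
        assert log[-1]["total"] < log[0]["total"]
        assert max(r["max_gt_count_error"] for r in log) <= 1e-4
        assert all(r["generator_grad_norm"] > 0 for r in log)

    def test_determinism_same_seed_same_curve(self):
        swin_cfg, mfen_cfg = default_tiny_configs()
        data = make_scenes(2, size=64, seed0=5)
        curves = []
        for _ in range(2):
            rng = np.random.default_rng(1)
            generator = KernelGenerator(swin_cfg, rng=rng)
            counter = MFEN(mfen_cfg, rng=rng)
            config = TrainConfig(seed=7, batch_size=2)
            log = train_joint(data, generator, counter, config, steps=3, lr=1e-4)
            curves.append([r["total"] for r in log])
        assert curves[0] == curves[1]

    def test_empty_dataset_rejected(self):
        swin_cfg, mfen_cfg = default_tiny_configs()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            train_joint([], KernelGenerator(swin_cfg, rng=rng), MFEN(mfen_cfg, rng=rng), TrainConfig())


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr=0)
    with pytest.raises(ValueError):
        TrainConfig(zeta=0)
    with pytest.raises(ValueError):
        TrainConfig(lam=-1)
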