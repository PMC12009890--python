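"""Counting network: frontend, DRM residual identities, CBAM, fusion, params."""

import numpy as np
import pytest

from densecount.autodiff import Tensor
from densecount.geometry import Schedule, gridding_coverage, hdc_valid
from densecount.mfen import (
    CBAM,
    DRM1,
    DRM2,
    DRM3,
    MFEN,
    Frontend,
    MFENConfig,
    count_from_density,
    count_parameters,
    mfen_forward,
)

TINY = MFENConfig(column_width=16, frontend_channels=32, cbam_reduction=4)


@pytest.fixture(scope="module")
def tiny_model():
    return MFEN(TINY, rng=np.random.default_rng(0))


class TestFrontend:
    def test_output_shape_stride_8(self):
        fe = Frontend(TINY.frontend_plan, np.random.default_rng(0))
        out = fe(Tensor(np.random.default_rng(1).random((1, 3, 64, 64))))
        assert out.shape == (1, TINY.frontend_channels, 8, 8)

    def test_default_parameter_count_matches_closed_form(self):
        fe = Frontend(MFENConfig().frontend_plan, np.random.default_rng(0))
        # sum over the 10 VGG-16 conv layers of Cin*Cout*9 + Cout
        plan = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512)
        expected, cin = 0, 3
        for cout in plan:
            expected += cin * cout * 9 + cout
            cin = cout
        assert fe.num_parameters() == expected == 7_635_264

    def test_zero_input_zero_biases_zero_output(self):
        fe = Frontend(TINY.frontend_plan, np.random.default_rng(0))
        for conv in fe.convs:
            conv.bias.data[:] = 0.0
        out = fe(Tensor(np.zeros((1, 3, 32, 32))))
        np.testing.assert_array_equal(out.data, 0.0)


def _identity_residual(module, channels):
    """Zero all non-residual convs; make the 1x1 residual the identity."""
    for name in ("a", "b", "pre", "dilated"):
        conv = getattr(module, name, None)
        if conv is not None:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
    module.residual.weight.data[:] = np.eye(channels).reshape(channels, channels, 1, 1)
    module.residual.bias.data[:] = 0.0


@pytest.mark.parametrize("cls", [DRM1, DRM2, DRM3])
class TestDRMs:
    def _build(self, cls, rng):
        if cls is DRM1:
            return cls(16, 16, 3, 2, rng)
        return cls(16, 3, 2, rng)

    def test_output_width_is_column_width(self, cls):
        module = self._build(cls, np.random.default_rng(0))
        out = module(Tensor(np.random.default_rng(1).random((2, 16, 10, 10))))
        assert out.shape == (2, 16, 10, 10)

    def test_residual_identity(self, cls):
        module = self._build(cls, np.random.default_rng(2))
        _identity_residual(module, 16)
        x = np.random.default_rng(3).random((1, 16, 8, 8))  # non-negative input
        out = module(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_zero_input_zero_bias_zero_output(self, cls):
        module = self._build(cls, np.random.default_rng(4))
        for _, p in module.named_parameters():
            if p.ndim == 1:
                p.data[:] = 0.0
        out = module(Tensor(np.zeros((1, 16, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)


class TestCBAM:
    def test_zero_input_zero_output(self):
        cbam = CBAM(16, reduction=4, rng=np.random.default_rng(0))
        out = cbam(Tensor(np.zeros((1, 16, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_zero_logits_quarter_passthrough(self):
        cbam = CBAM(16, reduction=4, rng=np.random.default_rng(1))
        for _, p in cbam.named_parameters():
            p.data[:] = 0.0  # all attention logits 0 -> both gates sigmoid(0)=0.5
        x = np.random.default_rng(2).random((1, 16, 8, 8))
        out = cbam(Tensor(x))
        np.testing.assert_allclose(out.data, x / 4.0, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self):
        cbam = CBAM(16, reduction=4, rng=np.random.default_rng(3))
        x = Tensor(np.random.default_rng(4).random((1, 16, 8, 8)))
        cg = cbam._channel_gate(x).data
        sg = cbam._spatial_gate(x).data
        assert ((cg > 0) & (cg < 1)).all() and ((sg > 0) & (sg < 1)).all()
        assert cbam(x).shape == x.shape


class TestMFEN:
    def test_forward_contract(self, tiny_model):
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        out = tiny_model(x)
        assert out.shape == (1, 1, 8, 8)
        assert (out.data >= 0).all()

    def test_deterministic(self, tiny_model):
        image = np.random.default_rng(1).random((48, 48, 3))
        a = mfen_forward(tiny_model, image)
        b = mfen_forward(tiny_model, image)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.isfinite(a.values).all()

    def test_density_map_stride_and_count(self, tiny_model):
        image = np.random.default_rng(2).random((64, 64, 3))
        dmap = mfen_forward(tiny_model, image)
        assert dmap.stride == 8
        assert count_from_density(dmap) == pytest.approx(dmap.values.sum())

    def test_translation_covariance_at_stride_8(self):
        # a config with a modest receptive field so the 320 px image has an
        # interior unaffected by the wrapped border (schedule rf 19 cells)
        config = MFENConfig(
            column_kernels=(3, 3, 3),
            dilation_schedules=((1, 2, 3, 1, 2),) * 3,
            column_width=16,
            frontend_channels=32,
            cbam_reduction=4,
        )
        model = MFEN(config, rng=np.random.default_rng(7))
        rng = np.random.default_rng(3)
        # constant border band keeps CBAM's global channel descriptors identical
        # between the two inputs, so the comparison isolates pure translation;
        # the patch sits far enough in that its influence zone stays clear of
        # the zero-padding border band
        base = np.full((560, 560, 3), 0.5)
        base[240:320, 240:320] = rng.random((80, 80, 3))
        shifted = np.roll(base, (8, 8), axis=(0, 1))
        m0 = mfen_forward(model, base).values
        m1 = mfen_forward(model, shifted).values
        margin = 16  # > half the total receptive field in stride-8 cells
        np.testing.assert_allclose(
            m1[margin + 1 : -margin, margin + 1 : -margin],
            m0[margin:-margin - 1, margin:-margin - 1],
            atol=1e-4,
        )


class TestConfigAndParams:
    def test_default_schedules_are_hdc_valid_and_hole_free(self):
        config = MFENConfig()
        for k, sched in zip(config.column_kernels, config.dilation_schedules):
            assert hdc_valid(sched)
            used, footprint = gridding_coverage(Schedule.uniform(k, sched[:3]))
            assert used == footprint

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MFENConfig(dilation_schedules=((2, 4, 8, 2, 4),) * 3)
        with pytest.raises(ValueError):
            MFENConfig(column_width=18)

    def test_parameter_count_near_13_08M(self):
        total = count_parameters()
        assert abs(total / 1e6 - 13.08) / 13.08 < 0.01

    def test_parameter_count_is_pure_function_of_config(self):
        assert count_parameters(TINY) == count_parameters(TINY)

    def test_all_kernels_3_strictly_fewer_parameters(self):
        smaller = MFENConfig(column_kernels=(3, 3, 3))
        assert count_parameters(smaller) < count_parameters()
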