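import numpy as np
import pytest

from ictalnet import nn
from ictalnet.models import (
    ARCHITECTURES,
    BatchNormParams,
    ConstructionError,
    ConvGeometry,
    ModelSpec,
    batch_normalize,
    build_model,
    conv_output_size,
    count_parameters,
    se_recalibrate,
)

CWT_HW = (22, 2560)
STFT_HW = (129, 39)


class TestConvOutputSize:
    @pytest.mark.parametrize("geom,expected", [
        (ConvGeometry(22, 22, 1, 1), (22, 22)),
        (ConvGeometry(2560, 2560, 3, 3), (2558, 2558)),
        (ConvGeometry(39, 39, 16, 16), (24, 24)),
        (ConvGeometry(10, 10, 3, 3, padding=1, stride=2), (5, 5)),
    ])
    def test_floor_division_semantics(self, geom, expected):
        assert conv_output_size(geom) == expected

    def test_kernel_larger_than_padded_input_raises(self):
        with pytest.raises(ValueError, match="larger than padded input"):
            conv_output_size(ConvGeometry(4, 4, 6, 6))

    def test_matches_empirical_conv_shapes(self):
        rng = np.random.default_rng(0)
        for kh, kw, p, s in [(3, 16, 0, 1), (2, 5, 1, 2), (1, 7, 0, 3)]:
            conv = nn.Conv2d(1, 1, (kh, kw), stride=(s, s), padding=(p, p), rng=rng)
            out = conv.forward(np.zeros((1, 1, 20, 40), np.float32))
            oh, ow = conv_output_size(ConvGeometry(20, 40, kh, kw, p, s))
            assert out.shape[2:] == (oh, ow)


class TestBatchNormalize:
    def test_standardizes_large_batch(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, (2000, 4))
        y = batch_normalize(x, BatchNormParams())
        assert np.abs(y.mean(axis=0)).max() < 1e-6
        assert np.abs(y.var(axis=0) - 1).max() < 1e-3

    def test_constant_batch_maps_to_beta(self):
        y = batch_normalize(np.full((8, 3), 5.0), BatchNormParams(beta=2.0))
        np.testing.assert_allclose(y, 2.0, atol=1e-6)

    def test_affine_transport_of_moments(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5000, 1))
        y = batch_normalize(x, BatchNormParams(gamma=2.0, beta=5.0))
        assert y.mean() == pytest.approx(5.0, abs=1e-6)
        assert y.std() == pytest.approx(2.0, rel=1e-3)

    def test_eps_must_be_positive(self):
        with pytest.raises(ValueError):
            BatchNormParams(eps=0.0)


class TestSERecalibrate:
    def test_identical_channels_with_tied_weights_get_equal_scaling(self):
        se = nn.SEBlock(4, 2, rng=np.random.default_rng(0))
        # tie the excitation: identical rows -> symmetric in channels
        se.w1.data[...] = 0.1
        se.w2.data[...] = 0.2
        x = np.tile(np.random.default_rng(1).standard_normal((1, 1, 3, 3)), (1, 4, 1, 1))
        s = se.channel_weights(x.astype(np.float32))
        assert np.ptp(s) < 1e-7

    def test_weights_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        se = nn.SEBlock(8, 4, rng=rng)
        s = se.channel_weights(rng.standard_normal((2, 8, 5, 5)).astype(np.float32))
        assert np.all(s > 0) and np.all(s < 1)

    def test_functional_form_shape_and_error(self):
        out = se_recalibrate(np.ones((8, 2, 2), np.float32), reduction=4)
        assert out.shape == (8, 2, 2)
        with pytest.raises(ValueError):
            nn.SEBlock(2, 8)


class TestBuildModel:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    @pytest.mark.parametrize("hw", [CWT_HW, STFT_HW])
    def test_builds_and_classifies_for_both_geometries(self, arch, hw):
        spec = ModelSpec(architecture=arch, in_channels=5, input_hw=hw)
        model = build_model(spec, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 5, *hw)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (2, 2)
        proba = model.predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_construction_error_names_offending_stage(self):
        spec = ModelSpec(architecture="eegnet_se", in_channels=2,
                         input_hw=(4, 6), adaptive_kernels=False)
        with pytest.raises(ConstructionError, match="temporal_conv"):
            build_model(spec)

    def test_shape_trace_matches_conv_output_size_composition(self):
        spec = ModelSpec(architecture="shallow_convnet", in_channels=3,
                         input_hw=CWT_HW)
        model = build_model(spec)
        trace = dict(model.shape_trace)
        h, w = CWT_HW
        # temporal conv: kernel (1, 25), stride (1, 4) on the long time axis
        _, w = conv_output_size(ConvGeometry(h, w, 1, 25, 0, 4))
        assert trace["temporal_conv"] == (16, h, w)
        # full-frequency depthwise: kernel (22, 1)
        h2, _ = conv_output_size(ConvGeometry(h, w, h, 1))
        assert trace["full_freq_depthwise"] == (16, 1, w)
        # time pooling: kernel 75, stride 15
        _, w3 = conv_output_size(ConvGeometry(1, w, 1, 75, 0, 15))
        assert trace["time_avgpool"][2] == w3

    def test_dropout_zero_forward_is_deterministic(self):
        spec = ModelSpec(architecture="shallow_convnet", in_channels=2,
                         input_hw=STFT_HW, dropout_rate=0.0)
        model = build_model(spec, seed=1)
        x = np.random.default_rng(2).standard_normal((3, 2, *STFT_HW)).astype(np.float32)
        model.train(True)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_state_dict_roundtrip(self, tmp_path):
        spec = ModelSpec(architecture="shallow_convnet", in_channels=2, input_hw=STFT_HW)
        model = build_model(spec, seed=3)
        x = np.random.default_rng(0).standard_normal((2, 2, *STFT_HW)).astype(np.float32)
        ref = model.predict_logits(x)
        model.save(tmp_path / "w.npz")
        other = build_model(spec, seed=99)
        other.load(tmp_path / "w.npz")
        np.testing.assert_array_equal(other.predict_logits(x), ref)


class TestCountParameters:
    def test_compact_model_is_lighter_than_baseline(self):
        for hw in (CWT_HW, STFT_HW):
            small = build_model(ModelSpec(architecture="eegnet_se", in_channels=23,
                                          input_hw=hw))
            big = build_model(ModelSpec(architecture="alexnet_baseline",
                                        in_channels=23, input_hw=hw))
            assert count_parameters(small) < count_parameters(big)

    def test_count_invariant_to_batch_size(self):
        spec = ModelSpec(architecture="shallow_convnet", in_channels=2, input_hw=STFT_HW)
        model = build_model(spec)
        n0 = count_parameters(model)
        for b in (1, 4):
            model.forward(np.zeros((b, 2, *STFT_HW), np.float32))
            assert count_parameters(model) == n0

    def test_depthwise_layer_matches_closed_form(self):
        spec = ModelSpec(architecture="eegnet_se", in_channels=4, input_hw=STFT_HW)
        model = build_model(spec)
        dw = next(l for l in model.net.layers
                  if isinstance(l, nn.Conv2d) and l.name == "separable_depthwise")
        kh, kw = dw.kernel
        expected = dw.out_channels * 1 * kh * kw  # groups == channels, no bias
        assert dw.weight.data.size == expected
        assert dw.bias is None
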