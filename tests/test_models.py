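"""Network builders: shapes, parameter census anchors, freezing, prediction."""

import numpy as np
import pytest

from tumorseg import nn
from tumorseg.models import (
    ModelConfig,
    build_model,
    build_proposed,
    build_unet,
    build_vgg19_unet,
    count_parameters,
    load_weights,
    predict_mask,
    save_weights,
    summary_table,
)
from tumorseg.phantoms import PhantomSpec, generate_phantom


def closed_form_proposed_decoder(widths=(128, 64, 32, 16), units=6, r=16,
                                 skips=(512, 256, 128, 64), bridge=512):
    """Independent layer-by-layer arithmetic for the proposed decoder."""
    trainable = 0
    c = bridge
    for w, skip in zip(widths, skips):
        trainable += 4 * c + c + c * w + w            # separable transposed conv
        cat = w + skip
        red = max(1, cat // r)
        trainable += cat * red + red + red * cat + cat  # channel-attention MLP
        trainable += 7 * 7 * 2 + 2 + 2 * 1 + 1          # separable spatial conv
        uc = cat
        for _ in range(units):
            trainable += 9 * uc + uc + uc * w + w + 2 * w
            uc = w
        c = w
    trainable += widths[-1] + 1                        # 1x1 head
    non_trainable = 2 * units * sum(widths)
    return trainable, non_trainable


VGG19_STACK = 20_024_384  # sum over the 16 conv layers of 3*3*Cin*Cout + Cout


class TestCensusAnchors:
    def test_classic_unet_trainable_rounds_to_31_million(self):
        census = count_parameters(build_unet())
        assert round(census.trainable / 1e6, 1) == 31.0
        assert census.trainable == 31_031_745  # frozen closed-form expectation

    def test_vgg19_encoder_stack_parameter_count(self):
        net = build_vgg19_unet()
        trainable, _ = nn.count_params(net.encoder)
        assert trainable == VGG19_STACK

    def test_vgg19_unet_five_skip_tap_offs(self):
        net = build_vgg19_unet(ModelConfig(architecture="vgg19_unet",
                                           input_height=64, input_width=64,
                                           width_multiplier=0.25,
                                           decoder_widths=(128, 64, 32, 16)))
        from tumorseg.nn.tensor import Tensor

        skips, bridge = net.encoder(Tensor(np.zeros((1, 64, 64, 3), dtype=np.float32)))
        assert len(skips) + 1 == 5  # one tap-off per VGG19 block

    def test_vgg19_unet_batchnorm_non_trainable_count(self):
        assert count_parameters(build_vgg19_unet()).non_trainable == 3840

    def test_proposed_census_matches_closed_form(self):
        census = count_parameters(build_proposed())
        dec_t, dec_nt = closed_form_proposed_decoder()
        assert census.non_trainable == dec_nt == 2880
        assert census.trainable == VGG19_STACK + dec_t
        assert round(census.trainable / 1e5) / 10 == 20.4  # 3 s.f.

    def test_lightness_ordering(self):
        proposed = count_parameters(build_proposed()).trainable
        vgg = count_parameters(build_vgg19_unet()).trainable
        assert proposed < vgg < 41.0e6  # residual U-Net published figure


class TestCensusMechanics:
    def test_single_conv_parameter_count(self):
        conv = nn.Conv2D(3, 64, 3, np.random.default_rng(0))
        assert nn.count_params(conv) == (1792, 0)

    def test_frozen_encoder_counts_as_non_trainable(self):
        cfg = ModelConfig(architecture="proposed", encoder_trainable=False)
        census = count_parameters(build_proposed(cfg))
        assert census.non_trainable == VGG19_STACK + 2880
        assert census.trainable + census.non_trainable == census.total

    def test_width_multiplier_quadratic_shrink(self):
        full = count_parameters(build_unet()).trainable
        small_cfg = ModelConfig(architecture="unet", width_multiplier=0.125)
        small = count_parameters(build_unet(small_cfg)).trainable
        # conv parameters scale with Cin*Cout -> about (1/8)^2
        assert full / small == pytest.approx(64, rel=0.15)

    def test_flops_positive_and_scale_with_resolution(self):
        cfg64 = ModelConfig(architecture="unet", input_height=64, input_width=64,
                            width_multiplier=0.25)
        cfg128 = ModelConfig(architecture="unet", input_height=128, input_width=128,
                             width_multiplier=0.25)
        f64 = count_parameters(build_unet(cfg64)).flops
        f128 = count_parameters(build_unet(cfg128)).flops
        assert f64 > 0 and f128 == pytest.approx(4 * f64, rel=0.01)

    def test_summary_table_totals_match_census(self):
        cfg = ModelConfig(architecture="proposed", input_height=64, input_width=64,
                          width_multiplier=0.25, decoder_widths=(64, 32, 16, 8))
        net = build_proposed(cfg)
        census = count_parameters(net)
        assert summary_table(net)["params"].sum() == census.total


@pytest.mark.parametrize("arch", ["unet", "vgg19_unet", "proposed"])
def test_forward_pass_finite_probabilities(arch, rng):
    cfg = ModelConfig(architecture=arch, input_height=64, input_width=64,
                      width_multiplier=0.25, decoder_widths=(64, 32, 16, 8))
    net = build_model(cfg, seed=1)
    probs = net.predict(rng.random((2, 64, 64, 3)).astype(np.float32))
    assert probs.shape == (2, 64, 64)
    assert np.isfinite(probs).all()
    assert (probs > 0).all() and (probs < 1).all()


@pytest.fixture(scope="module")
def net_and_sample():
    cfg = ModelConfig(architecture="proposed", input_height=32, input_width=32,
                      width_multiplier=0.125)
    net = build_proposed(cfg, seed=0)
    spec = PhantomSpec(image_height=32, image_width=32, tumor_probability=1.0,
                       tumor_semi_axes_range=(4.0, 9.0), seed=2)
    return net, generate_phantom(spec, 0)


class TestPredictMask:

    def test_mask_shape_and_binary(self, net_and_sample):
        net, sample = net_and_sample
        mask = predict_mask(net, sample)
        assert mask.shape == sample.mask.shape
        assert set(np.unique(mask)) <= {0, 1}

    def test_unattainable_threshold_gives_empty_mask(self, net_and_sample):
        net, sample = net_and_sample
        assert predict_mask(net, sample, threshold=1.01).sum() == 0

    def test_shape_mismatch_rejected(self, net_and_sample):
        net, _ = net_and_sample
        spec = PhantomSpec(image_height=64, image_width=64, seed=3)
        with pytest.raises(ValueError, match="does not match"):
            predict_mask(net, generate_phantom(spec, 0))

    def test_checkpoint_roundtrip(self, net_and_sample, tmp_path):
        net, sample = net_and_sample
        probs_before = net.predict(sample.image[None])
        save_weights(net, tmp_path / "w.npz")
        cfg = ModelConfig(architecture="proposed", input_height=32, input_width=32,
                          width_multiplier=0.125)
        other = build_proposed(cfg, seed=99)
        load_weights(other, tmp_path / "w.npz")
        np.testing.assert_array_equal(other.predict(sample.image[None]), probs_before)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(architecture="resnet_unet").validate()
    with pytest.raises(ValueError):
        ModelConfig(input_height=100).validate()  # not divisible by 16
    with pytest.raises(ValueError):
        ModelConfig(decoder_widths=(64, 64, 32, 16)).validate()  # not decreasing
    with pytest.raises(ValueError):
        ModelConfig(dropout_rate=1.0).validate()
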