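"""Architecture contracts: shapes, activations, parameter counts, gradients."""

import numpy as np
import pytest

from hypnonet.model import (
    ConfigError,
    ModelConfig,
    SleepNet,
    _MSACB,
    frame_cnn_forward,
    epoch_hybrid_forward,
    frame_skip_forward,
    load_checkpoint,
    mish,
    model_forward,
    save_checkpoint,
    sequence_forward,
)
from hypnonet.nn import Tensor
from hypnonet.train import FocalLossParams, focal_loss_tensor


class TestMish:
    def test_zero_and_saturation(self):
        assert mish(0.0) == 0.0
        assert abs(mish(20.0) - 20.0) < 1e-6

    def test_matches_high_precision_formula(self):
        # x * tanh(ln(1 + e^x)) at x = -1, evaluated in extended precision
        assert abs(mish(-1.0) - (-0.303401461374108918)) < 1e-12

    def test_stable_for_large_magnitudes(self):
        out = mish(np.array([-1e4, -50.0, 50.0, 1e4]))
        assert np.isfinite(out).all()
        assert out[-1] == pytest.approx(1e4)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_elementwise_on_tensors(self):
        x = np.linspace(-5, 5, 11)
        t = Tensor(x).mish()
        assert np.allclose(t.data, [mish(v) for v in x])


class TestModelConfig:
    def test_equal_product_violation_rejected_at_construction(self):
        with pytest.raises(ConfigError, match="equal-product"):
            ModelConfig(small_pool=8, small_stride=3, large_pool=2,
                        large_stride=11)

    def test_residual_width_must_match_lstm(self):
        with pytest.raises(ConfigError, match="residual"):
            ModelConfig(residual_fc_units=1000)

    def test_default_shape_arithmetic(self):
        cfg = ModelConfig()
        # ceil(ceil(3000/3)/8) = ceil(ceil(3000/12)/2) = 125
        assert cfg.frame_steps == 125
        assert cfg.feature_width == 1024 + 1024 + 1024

    def test_doubling_fs_with_scaled_strides_preserves_steps(self):
        cfg = ModelConfig(fs=200, small_kernel=50, large_kernel=200,
                          small_stride=6, large_stride=24)
        assert cfg.epoch_samples == 6000
        assert cfg.frame_steps == 125

    def test_yaml_roundtrip(self, tmp_path, tiny_cfg):
        tiny_cfg.to_yaml(tmp_path / "cfg.yaml")
        back = ModelConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == tiny_cfg


def expected_parameter_count(c: ModelConfig) -> int:
    """Layer-by-layer parameter formula, independent of the implementation."""
    F, N = c.frame_channels, c.msacb_branch_channels
    B, E = c.epoch_bottleneck_channels, c.epoch_cnn_channels
    Hg, Hl = c.gru_hidden, c.lstm_hidden
    S, R, C = c.skip_channels, c.residual_fc_units, c.n_classes
    D = c.feature_width

    def conv(cin, cout, k):
        return cout * cin * k + cout

    total = conv(1, F, c.small_kernel) + conv(1, F, c.large_kernel)
    # MSACB: four 1x1 entries + 1+2+3 = 6 dilated kernel-3 convs
    total += 4 * conv(2 * F, N, 1) + 6 * conv(N, N, 3)
    total += conv(4 * N, S, 1)                       # frame skip
    total += conv(4 * N, B, 1) + conv(B, E, 3)       # epoch CNN branch
    total += conv(4 * N, B, 1)                       # epoch RNN bottleneck
    total += 2 * (B * 3 * Hg + Hg * 3 * Hg + 3 * Hg)  # Bi-GRU, both directions
    total += D * C + C                               # pretraining head
    total += D * R + R                               # sequence residual FC
    total += 2 * (D * 4 * Hl + Hl * 4 * Hl + 4 * Hl)         # Bi-LSTM layer 1
    for _ in range(c.lstm_layers - 1):
        total += 2 * (2 * Hl * 4 * Hl + Hl * 4 * Hl + 4 * Hl)  # deeper layers
    total += R * C + C                               # output FC
    return total


@pytest.mark.parametrize("cfg_factory", [ModelConfig.tiny, ModelConfig],
                         ids=["tiny", "default"])
def test_parameter_count_matches_independent_formula(cfg_factory):
    cfg = cfg_factory()
    model = SleepNet(cfg, seed=0)
    assert model.n_parameters() == expected_parameter_count(cfg)


class TestFrameLevel:
    def test_both_branches_yield_equal_steps(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        fm = frame_cnn_forward(np.random.default_rng(0).normal(size=3000),
                               model)
        assert fm.level == "frame"
        assert fm.values.shape == (1, tiny_cfg.msacb_channels,
                                   tiny_cfg.frame_steps)

    def test_zero_input_zero_biases_gives_zero_output(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)  # biases are zero-initialised
        fm = frame_cnn_forward(np.zeros(3000), model)
        assert np.allclose(fm.values.data, 0.0)
        assert np.allclose(frame_skip_forward(fm, model), 0.0)
        cnn, rnn = epoch_hybrid_forward(fm, model)
        assert np.allclose(cnn, 0.0)
        assert np.allclose(rnn, 0.0)

    def test_wrong_epoch_length_rejected(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="30"):
            frame_cnn_forward(np.zeros(2999), model)


class TestMSACB:
    def test_time_length_preserved(self):
        rng = np.random.default_rng(0)
        block = _MSACB(8, 4, (1, 2, 4), rng)
        for t in (15, 40, 125):
            out = block(Tensor(rng.normal(size=(1, 8, t))))
            assert out.shape == (1, 16, t)

    def test_branch_depths(self):
        block = _MSACB(4, 2, (1, 2, 4), np.random.default_rng(0))
        assert [len(b) for b in block.branches] == [1, 2, 3, 4]

    def test_receptive_field_by_gradient_support(self):
        # deepest branch: 1x1 then kernel-3 dilations 1,2,4 -> 15 taps
        block = _MSACB(1, 1, (1, 2, 4), np.random.default_rng(3))
        x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 41)),
                   requires_grad=True)
        out = block(x)
        out[:, 3, 20].sum().backward()
        support = np.flatnonzero(np.abs(x.grad[0, 0]) > 0)
        assert support.max() - support.min() + 1 == 15
        assert support.min() == 20 - 7 and support.max() == 20 + 7

    def test_too_few_dilations_rejected(self):
        with pytest.raises(ConfigError, match="dilation"):
            ModelConfig(msacb_dilations=(1, 2))


class TestEpochAndSequenceLevels:
    def test_hybrid_outputs_have_configured_widths(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        fm = frame_cnn_forward(np.random.default_rng(1).normal(size=3000),
                               model)
        cnn, rnn = epoch_hybrid_forward(fm, model)
        assert cnn.shape == (tiny_cfg.epoch_cnn_channels,)
        assert rnn.shape == (2 * tiny_cfg.gru_hidden,)

    def test_sequence_softmax_rows(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        feats = np.random.default_rng(2).normal(
            size=(25, tiny_cfg.feature_width))
        out = sequence_forward(feats, model)
        assert out.probabilities.shape == (25, 5)
        assert np.abs(out.probabilities.sum(axis=1) - 1).max() < 1e-6
        assert (out.probabilities > 0).all()

    def test_single_epoch_sequence_valid(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        out = sequence_forward(
            np.zeros((1, tiny_cfg.feature_width)), model)
        assert out.probabilities.shape == (1, 5)

    def test_wrong_feature_width_rejected(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="width"):
            sequence_forward(np.zeros((5, tiny_cfg.feature_width + 1)), model)

    def test_logit_shift_invariance_of_softmax(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        feats = np.random.default_rng(3).normal(
            size=(4, tiny_cfg.feature_width))
        out = sequence_forward(feats, model)
        shifted = Tensor(out.logits + 7.0).softmax(axis=-1)
        assert np.allclose(shifted.data, out.probabilities, atol=1e-12)


class TestModelForward:
    def test_batch_shape_composition(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        x = np.random.default_rng(4).normal(size=(2, 6, 3000))
        for mode in ("full", "pretrain"):
            out = model_forward(x, model, mode=mode)
            assert out.probabilities.shape == (2, 6, 5)
            assert np.abs(out.probabilities.sum(-1) - 1).max() < 1e-6

    def test_inference_is_deterministic(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        x = np.random.default_rng(5).normal(size=(1, 3, 3000))
        a = model_forward(x, model, mode="full").probabilities
        b = model_forward(x, model, mode="full").probabilities
        assert np.abs(a - b).max() < 1e-7

    def test_invalid_mode_rejected(self, tiny_cfg):
        model = SleepNet(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="mode"):
            model_forward(np.zeros((1, 2, 3000)), model, mode="test")

    def test_gradient_reaches_first_convolution(self, tiny_cfg):
        # the skip/residual paths let sequence-level loss supervise the
        # earliest frame-level convolution directly
        model = SleepNet(tiny_cfg, seed=0)
        x = Tensor(np.random.default_rng(6).normal(size=(1, 3, 3000)))
        logits = model.forward_full(x)
        probs = logits.softmax(axis=-1)
        loss = focal_loss_tensor(probs, np.array([[0, 2, 3]]),
                                 FocalLossParams())
        loss.backward()
        assert model.conv_small.weight.grad is not None
        assert np.abs(model.conv_small.weight.grad).max() > 0
        assert np.abs(model.conv_large.weight.grad).max() > 0


def test_checkpoint_roundtrip_and_mismatch(tmp_path, tiny_cfg):
    model = SleepNet(tiny_cfg, seed=0)
    save_checkpoint(tmp_path / "m.npz", model, extra={"note": "t"})
    back, extra = load_checkpoint(tmp_path / "m.npz")
    assert extra == {"note": "t"}
    x = np.random.default_rng(7).normal(size=(1, 2, 3000))
    assert np.allclose(model_forward(x, model).probabilities,
                       model_forward(x, back).probabilities)
    other = ModelConfig.tiny(gru_hidden=4)
    with pytest.raises(ValueError, match="mismatch"):
        load_checkpoint(tmp_path / "m.npz", cfg=other)
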