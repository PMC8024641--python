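"""Network architecture: channel schedule, forward contracts, gating,
activation semantics, parameter-count oracle, ablation monotonicity,
reconstruction from config, and gradient flow across the configuration grid."""

import numpy as np
import pytest

from ctpm.model import (
    ModelConfig,
    build_model,
    load_checkpoint,
    prelu_scalar,
    save_checkpoint,
)
from ctpm.nn import Adam, Tensor, masked_bce
from ctpm.nn import core


TINY = dict(width_multiplier=3, kernel_size=3, n_residual_blocks=1, n_stride_convs=2)


def tiny_net(seed=0, **kw):
    cfg = ModelConfig(**{**TINY, **kw})
    return build_model(cfg, seed=seed)


class TestChannelSchedule:
    def test_paper_optimum_bottleneck_128(self):
        cfg = ModelConfig()  # defaults: width 4, 3 stride convs
        assert cfg.channel_schedule() == [32, 64, 96, 128]
        _, summ = build_model(cfg)
        assert summ.bottleneck_channels == 128

    @pytest.mark.parametrize("w,expected_last", [(3, 96), (4, 128), (5, 160)])
    def test_bottleneck_is_32w(self, w, expected_last):
        cfg = ModelConfig(width_multiplier=w)
        assert cfg.channel_schedule()[-1] == 32 * w == expected_last

    def test_two_level_schedule(self):
        cfg = ModelConfig(width_multiplier=3, n_stride_convs=2)
        assert cfg.channel_schedule() == [32, 64, 96]


class TestForward:
    def test_output_shape_and_range(self, rng):
        net, _ = tiny_net()
        x = rng.normal(size=(1, 1, 16, 12, 12)).astype(np.float32)
        roi = np.ones((1, 16, 12, 12))
        out = net(x, roi)
        assert out.data.shape == (1, 1, 16, 12, 12)
        assert out.data.min() > 0.0 and out.data.max() < 1.0

    def test_eval_mode_deterministic(self, rng):
        net, _ = tiny_net()
        net.eval()
        x = rng.normal(size=(1, 1, 16, 12, 12)).astype(np.float32)
        roi = np.ones((1, 16, 12, 12))
        a = net(x, roi).data
        b = net(x, roi).data
        assert np.array_equal(a, b)

    def test_zero_roi_makes_output_input_independent(self, rng):
        """With ROI attention, an all-zero mask zeroes every first-layer
        feature, so the prediction cannot depend on the CT at all."""
        net, _ = tiny_net()
        net.eval()
        roi = np.zeros((1, 16, 12, 12))
        a = net(rng.normal(size=(1, 1, 16, 12, 12)).astype(np.float32), roi).data
        b = net(rng.normal(size=(1, 1, 16, 12, 12)).astype(np.float32), roi).data
        assert np.array_equal(a, b)

    def test_indivisible_shape_reports_remainder(self, rng):
        net, _ = tiny_net()  # 2 stride convs -> divisor 4
        with pytest.raises(ValueError, match="remainder"):
            net(rng.normal(size=(1, 1, 15, 12, 12)).astype(np.float32),
                np.ones((1, 15, 12, 12)))

    def test_kernel_exceeding_deepest_map_rejected(self, rng):
        net, _ = tiny_net()  # kernel 3, 2 stride convs
        with pytest.raises(ValueError, match="kernel edge"):
            net(rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32),
                np.ones((1, 8, 8, 8)))

    def test_no_saturation_at_init(self):
        """Freshly Kaiming-initialized nets on a constant input produce
        mid-range outputs (mean in (0.05, 0.95)) across 20 seeds."""
        x = np.full((1, 1, 12, 12, 12), 0.5, dtype=np.float32)
        roi = np.ones((1, 12, 12, 12))
        for seed in range(20):
            net, _ = tiny_net(seed=seed)
            net.eval()
            mean = float(net(x, roi).data.mean())
            assert 0.05 < mean < 0.95, f"seed {seed}: saturated mean {mean}"


class TestPRelu:
    def test_positive_branch(self):
        assert prelu_scalar(2.0, 0.1) == 2.0

    def test_negative_branch(self):
        assert prelu_scalar(-2.0, 0.1) == pytest.approx(-0.2)

    def test_prelu_with_fixed_half_slope_equals_leaky(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 5, 5, 5)).astype(np.float32))
        a = Tensor(np.full(4, 0.5, dtype=np.float32))
        assert np.array_equal(core.prelu(x, a).data, core.leaky_relu(x, 0.5).data)


class TestParameterCount:
    def test_matches_layerwise_hand_count(self):
        """Independent layer-by-layer arithmetic for a small configuration
        (width 3, kernel 3, 1 residual block, 3 stride levels)."""
        cfg = ModelConfig(width_multiplier=3, kernel_size=3,
                          n_residual_blocks=1, n_stride_convs=3)
        net, summ = build_model(cfg)

        conv = lambda cin, cout, k: cout * (cin * k**3 + 1)
        bn = lambda c: 2 * c
        act = lambda c: c  # per-channel PReLU slope
        convt = lambda cin, cout: cin * cout * 8 + cout
        gate = lambda c: 2 * (max(1, c // 2) * (c + 1)) + (max(1, c // 2) + 1)
        block = lambda cin, cout, k: conv(cin, cout, k) + bn(cout) + act(cout)

        ch = [32, 53, 75, 96]  # round(32 * (1 + d*2/3))
        expected = block(1, ch[0], 3)
        for d in (1, 2, 3):
            expected += block(ch[d - 1], ch[d], 2)  # stride conv
            expected += block(ch[d], ch[d], 3)
        # one residual block: two conv+BN stages, one shared dropout, two acts
        expected += conv(ch[3], ch[3], 3) + bn(ch[3]) + act(ch[3])
        expected += conv(ch[3], ch[3], 3) + bn(ch[3]) + act(ch[3])
        for d in (3, 2, 1):
            expected += convt(ch[d], ch[d - 1]) + bn(ch[d - 1]) + act(ch[d - 1])
            if d - 1 in (0, 1):
                expected += gate(ch[d - 1])
            expected += block(2 * ch[d - 1], ch[d - 1], 3)
        expected += conv(ch[0], 1, 1)

        assert summ.parameter_count == expected

    def test_each_component_ablation_reduces_parameters(self):
        base = ModelConfig(**TINY)
        full = build_model(base)[1].parameter_count
        for key in ("use_residual", "use_roi_attention", "use_skip_attention"):
            cfg = ModelConfig(**{**TINY, key: False})
            ablated = build_model(cfg)[1].parameter_count
            if key == "use_roi_attention":
                # the ROI gate is parameter-free multiplicative masking
                assert ablated == full
            else:
                assert ablated < full


class TestReconstruction:
    def test_rebuild_from_config_identical_summary(self):
        cfg = ModelConfig(**TINY)
        _, a = build_model(cfg, seed=3)
        _, b = build_model(ModelConfig.from_dict(cfg.to_dict()), seed=3)
        assert a == b

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net, _ = tiny_net(seed=5)
        net.eval()
        x = rng.normal(size=(1, 1, 16, 12, 12)).astype(np.float32)
        roi = np.ones((1, 16, 12, 12))
        before = net(x, roi).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        restored = load_checkpoint(path)
        restored.eval()
        assert np.array_equal(restored(x, roi).data, before)
        assert restored.summary() == net.summary()


def architecture_grid():
    """The 12 architecture-grid configurations (width, kernel, dropout,
    activation and component ablations), at reduced depth for runtime."""
    small = dict(n_stride_convs=2, n_residual_blocks=2)
    return [
        ModelConfig(width_multiplier=3, kernel_size=5, **small),
        ModelConfig(width_multiplier=4, kernel_size=5, **small),
        ModelConfig(width_multiplier=5, kernel_size=5, **small),
        ModelConfig(kernel_size=5, dropout_rate=0.0, **small),
        ModelConfig(kernel_size=5, dropout_rate=0.2, **small),
        ModelConfig(kernel_size=5, dropout_rate=0.3, **small),
        ModelConfig(kernel_size=3, **small),
        ModelConfig(kernel_size=5, activation="leaky_relu", **small),
        ModelConfig(kernel_size=5, activation="relu", **small),
        ModelConfig(kernel_size=5, use_roi_attention=False, **small),
        ModelConfig(kernel_size=5, use_skip_attention=False, **small),
        ModelConfig(kernel_size=5, use_residual=False, **small),
    ]


@pytest.mark.parametrize("cfg", architecture_grid(),
                         ids=lambda c: f"w{c.width_multiplier}k{c.kernel_size}"
                                       f"d{c.dropout_rate}{c.activation}"
                                       f"{int(c.use_roi_attention)}"
                                       f"{int(c.use_skip_attention)}"
                                       f"{int(c.use_residual)}")
def test_gradient_flow_every_configuration(cfg):
    """Dead-branch detector: after one backward pass on a synthetic batch,
    every trainable parameter tensor holds a nonzero gradient."""
    net, _ = build_model(cfg, seed=1)
    rng = np.random.default_rng(2)
    shape = (20, 20, 20)  # deepest map 5x5x5 admits the kernel-5 rows
    x = rng.normal(size=(1, 1, *shape)).astype(np.float32)
    roi = (rng.random((1, *shape)) > 0.3).astype(np.float32)
    target = rng.random((1, 1, *shape)).astype(np.float32)
    net.zero_grad()
    out = net(x, roi)
    loss = masked_bce(out, target, np.ones((1, 1, *shape)))
    loss.backward()
    opt = Adam(net.parameters(), lr=1e-3)
    opt.step()
    for name, p in net.named_parameters():
        assert p.grad is not None, f"{name} received no gradient"
        assert np.abs(p.grad).max() > 0, f"{name} gradient identically zero"
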