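"""The configurable 3D encoder-decoder perfusion-mapping network.

Structure (full defaults): a 4-level encoder built from 2x2x2 stride-2
convolutions and 5x5x5 'same' convolutions, each followed by batch
normalization, a PReLU-family activation and spatial dropout; eight
channel-preserving residual blocks at the bottleneck; a symmetric decoder of
kernel-2 transposed convolutions; additive attention gates on the two
highest-resolution skip connections; an optional multiplicative ROI gate that
zeroes first-layer features outside the parenchyma mask; and a voxelwise
sigmoid output in [0, 1].

The channel count at depth ``d`` (0-based, ``L`` stride levels) is
``round(32 * (1 + d*(w-1)/L))`` for width multiplier ``w``, so the bottleneck
always has ``32*w`` channels (w=4 -> 32, 64, 96, 128).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import core
from .nn.core import Tensor

BASE_WIDTH = 32


@dataclass
class ModelConfig:
    """Every ablatable architecture choice.  Defaults reproduce the optimal
    configuration: width 4x32, kernel 5, dropout 0.1, PReLU, all components
    enabled."""

    width_multiplier: int = 4
    kernel_size: int = 5
    dropout_rate: float = 0.1
    activation: str = "prelu"  # prelu | leaky_relu | relu
    leaky_slope: float = 0.5
    use_residual: bool = True
    use_roi_attention: bool = True
    use_skip_attention: bool = True
    n_residual_blocks: int = 8
    n_stride_convs: int = 3

    def __post_init__(self) -> None:
        if self.width_multiplier < 1:
            raise ValueError("width_multiplier must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.activation not in ("prelu", "leaky_relu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.n_stride_convs < 1 or self.n_residual_blocks < 0:
            raise ValueError("invalid depth configuration")

    def channel_schedule(self) -> list[int]:
        w, L = self.width_multiplier, self.n_stride_convs
        return [int(round(BASE_WIDTH * (1 + d * (w - 1) / L))) for d in range(L + 1)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class NetworkSummary:
    channels: list[int]
    bottleneck_channels: int
    parameter_count: int
    receptive_field_edge: int
    config: dict = field(default_factory=dict)


class _ConvBlock(nn.Module):
    """conv -> BN -> activation -> dropout."""

    def __init__(self, cin, cout, k, stride, cfg: ModelConfig, rng):
        super().__init__()
        pad = k // 2 if stride == 1 else 0
        slope = {"prelu": 0.25, "leaky_relu": cfg.leaky_slope, "relu": 0.0}[cfg.activation]
        self.conv = self.add_child("conv", nn.Conv3d(cin, cout, k, stride, pad, rng, slope))
        self.bn = self.add_child("bn", nn.BatchNorm3d(cout))
        self.act = self.add_child("act", nn.Activation(cfg.activation, cout, cfg.leaky_slope))
        self.drop = self.add_child("drop", nn.Dropout3d(cfg.dropout_rate))

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.act(self.bn(self.conv(x))))


class _ResBlock(nn.Module):
    """conv-BN-act-dropout-conv-BN + identity, then act.  Channel-preserving."""

    def __init__(self, c, k, cfg: ModelConfig, rng):
        super().__init__()
        slope = {"prelu": 0.25, "leaky_relu": cfg.leaky_slope, "relu": 0.0}[cfg.activation]
        self.conv1 = self.add_child("conv1", nn.Conv3d(c, c, k, 1, k // 2, rng, slope))
        self.bn1 = self.add_child("bn1", nn.BatchNorm3d(c))
        self.act1 = self.add_child("act1", nn.Activation(cfg.activation, c, cfg.leaky_slope))
        self.drop = self.add_child("drop", nn.Dropout3d(cfg.dropout_rate))
        self.conv2 = self.add_child("conv2", nn.Conv3d(c, c, k, 1, k // 2, rng, slope))
        self.bn2 = self.add_child("bn2", nn.BatchNorm3d(c))
        self.act2 = self.add_child("act2", nn.Activation(cfg.activation, c, cfg.leaky_slope))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop(self.act1(self.bn1(self.conv1(x))))
        h = self.bn2(self.conv2(h))
        return self.act2(core.add(h, x))


class _AttentionGate(nn.Module):
    """Additive attention gate: the decoder feature (gating signal, same
    resolution after the transposed convolution) and the encoder skip are
    projected with 1x1x1 convolutions, summed, rectified, and squeezed to a
    sigmoid coefficient map that modulates the skip."""

    def __init__(self, c, cfg: ModelConfig, rng):
        super().__init__()
        ci = max(1, c // 2)
        self.wx = self.add_child("wx", nn.Conv3d(c, ci, 1, 1, 0, rng))
        self.wg = self.add_child("wg", nn.Conv3d(c, ci, 1, 1, 0, rng))
        self.psi = self.add_child("psi", nn.Conv3d(ci, 1, 1, 1, 0, rng))

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        a = core.leaky_relu(core.add(self.wx(skip), self.wg(gate)), 0.0)
        alpha = core.sigmoid(self.psi(a))
        return core.mul(skip, alpha)


class PerfusionNet(nn.Module):
    """CT -> perfusion network; see module docstring for the layer graph."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = int(seed)
        rng = np.random.default_rng([self.seed % (2**31), 101])
        self._dropout_rng = np.random.default_rng([self.seed % (2**31), 102])
        k, L = cfg.kernel_size, cfg.n_stride_convs
        ch = cfg.channel_schedule()
        self.channels = ch

        self.enc0 = self.add_child("enc0", _ConvBlock(1, ch[0], k, 1, cfg, rng))
        for d in range(1, L + 1):
            self.add_child(f"down{d}", _ConvBlock(ch[d - 1], ch[d], 2, 2, cfg, rng))
            self.add_child(f"enc{d}", _ConvBlock(ch[d], ch[d], k, 1, cfg, rng))
        if cfg.use_residual:
            for r in range(cfg.n_residual_blocks):
                self.add_child(f"res{r}", _ResBlock(ch[L], k, cfg, rng))
        for d in range(L, 0, -1):
            self.add_child(f"up{d}", nn.ConvTranspose3d(ch[d], ch[d - 1], 2, rng))
            self.add_child(f"upn{d}", nn.BatchNorm3d(ch[d - 1]))
            self.add_child(
                f"upa{d}", nn.Activation(cfg.activation, ch[d - 1], cfg.leaky_slope)
            )
            self.add_child(f"upd{d}", nn.Dropout3d(cfg.dropout_rate))
            if cfg.use_skip_attention and d - 1 in self._attention_levels():
                self.add_child(f"att{d - 1}", _AttentionGate(ch[d - 1], cfg, rng))
            self.add_child(f"dec{d - 1}", _ConvBlock(2 * ch[d - 1], ch[d - 1], k, 1, cfg, rng))
        self.out_conv = self.add_child("out_conv", nn.Conv3d(ch[0], 1, 1, 1, 0, rng))
        self._wire_dropout_rng()

    def _attention_levels(self) -> set[int]:
        # the two highest-resolution skips: small low-functional structures
        # only survive at fine resolution
        return {0, 1} if self.cfg.n_stride_convs >= 2 else {0}

    def _wire_dropout_rng(self) -> None:
        def visit(mod):
            if isinstance(mod, nn.Dropout3d):
                mod.rng = self._dropout_rng
            for child in mod._children.values():
                visit(child)

        visit(self)

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng([int(seed) % (2**31), 102])
        self._wire_dropout_rng()

    # ------------------------------------------------------------ forward
    def _check_shape(self, shape) -> None:
        L = self.cfg.n_stride_convs
        f = 2**L
        rem = [s % f for s in shape]
        if any(rem):
            raise ValueError(
                f"input shape {tuple(shape)} not divisible by 2^{L}={f}; "
                f"remainders {tuple(rem)}"
            )
        deepest = min(s // f for s in shape)
        if self.cfg.kernel_size > deepest:
            raise ValueError(
                f"kernel edge {self.cfg.kernel_size} exceeds the deepest "
                f"feature-map edge {deepest} for input {tuple(shape)}"
            )

    def __call__(self, ct: np.ndarray | Tensor, roi: np.ndarray) -> Tensor:
        x = ct if isinstance(ct, Tensor) else Tensor(ct[:, None] if ct.ndim == 4 else ct)
        if x.data.ndim != 5:
            raise ValueError("expected input of shape (N, 1, D, H, W) or (N, D, H, W)")
        self._check_shape(x.data.shape[2:])
        roi = np.asarray(roi, dtype=np.float32)
        if roi.ndim == 4:
            roi = roi[:, None]
        cfg = self.cfg
        L = cfg.n_stride_convs

        h = self.enc0(x)
        if cfg.use_roi_attention:
            h = core.mul_const(h, (roi > 0).astype(np.float32))
        skips = [h]
        for d in range(1, L + 1):
            h = self._children[f"down{d}"](h)
            h = self._children[f"enc{d}"](h)
            skips.append(h)
        if cfg.use_residual:
            for r in range(cfg.n_residual_blocks):
                h = self._children[f"res{r}"](h)
        for d in range(L, 0, -1):
            h = self._children[f"up{d}"](h)
            h = self._children[f"upn{d}"](h)
            h = self._children[f"upa{d}"](h)
            h = self._children[f"upd{d}"](h)
            skip = skips[d - 1]
            if cfg.use_skip_attention and d - 1 in self._attention_levels():
                skip = self._children[f"att{d - 1}"](skip, h)
            h = self._children[f"dec{d - 1}"](core.concat_channels(h, skip))
        return core.sigmoid(self.out_conv(h))

    def predict(self, ct: np.ndarray, roi: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode prediction (dropout off, running BN
        statistics); returns an array shaped like the spatial input."""
        was_training = self.training
        self.eval()
        try:
            out = self(ct, roi).data
        finally:
            self.train(was_training)
        return out[:, 0]

    # ------------------------------------------------------------ summary
    def summary(self) -> NetworkSummary:
        ch = self.channels
        return NetworkSummary(
            channels=list(ch),
            bottleneck_channels=ch[-1],
            parameter_count=self.n_parameters(),
            receptive_field_edge=self._receptive_field(),
            config=self.cfg.to_dict(),
        )

    def _receptive_field(self) -> int:
        """Receptive-field edge of one bottleneck voxel along the encoder
        path (strided and 'same' convolutions compose as rf += (k-1)*jump)."""
        rf, jump = 1, 1
        rf += (self.cfg.kernel_size - 1) * jump  # enc0
        for _ in range(self.cfg.n_stride_convs):
            rf += (2 - 1) * jump
            jump *= 2
            rf += (self.cfg.kernel_size - 1) * jump
        if self.cfg.use_residual:
            rf += 2 * self.cfg.n_residual_blocks * (self.cfg.kernel_size - 1) * jump
        return rf


def build_model(cfg: ModelConfig, seed: int = 0) -> tuple[PerfusionNet, NetworkSummary]:
    """Construct the network and its summary."""
    net = PerfusionNet(cfg, seed=seed)
    return net, net.summary()


def prelu_scalar(x: float, a: float) -> float:
    """Reference scalar activation: x if x > 0 else a*x."""
    return float(x) if x > 0 else float(a) * float(x)


# ------------------------------------------------------------- checkpoint
def save_checkpoint(net: PerfusionNet, path: str | Path) -> None:
    """Single-file .npz checkpoint with the model config embedded."""
    state = net.state_dict()
    meta = json.dumps({"config": net.cfg.to_dict(), "seed": net.seed})
    np.savez_compressed(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path: str | Path) -> PerfusionNet:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net = PerfusionNet(ModelConfig.from_dict(meta["config"]), seed=meta.get("seed", 0))
    net.load_state_dict(state)
    return net
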