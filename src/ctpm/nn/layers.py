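"""Layer modules over the autodiff core: convolutions with Kaiming-uniform
initialization, batch normalization with running statistics, PReLU-family
activations, spatial dropout, and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor


class Module:
    """Tiny module base: named parameters/buffers, recursive train/eval."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for cname, child in self._children.items():
            yield from child.named_parameters(f"{prefix}{cname}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for cname, child in self._children.items():
            yield from child.named_buffers(f"{prefix}{cname}.")

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for child in self._children.values():
            child.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # --- checkpointing -----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{n}": p.data.copy() for n, p in self.named_parameters()}
        state.update({f"buffer:{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float32).reshape(
                    params[name].data.shape
                )
            else:
                buffers[name][...] = np.asarray(value, dtype=np.float32).reshape(
                    buffers[name].shape
                )


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, a: float = 0.0):
    """He-style uniform initialization: bound = gain * sqrt(3 / fan_in) with
    gain = sqrt(2 / (1 + a^2)) for a rectifier of negative slope ``a``."""
    gain = np.sqrt(2.0 / (1.0 + a * a))
    bound = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 init_slope: float = 0.25):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.k = stride, pad, k
        fan_in = cin * k**3
        self.w = self.add_param("w", kaiming_uniform(rng, (cout, cin, k, k, k), fan_in, init_slope))
        bb = 1.0 / np.sqrt(fan_in)
        self.b = self.add_param("b", rng.uniform(-bb, bb, size=cout).astype(np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv3d(x, self.w, self.b, self.stride, self.pad)


class ConvTranspose3d(Module):
    def __init__(self, cin: int, cout: int, stride: int = 2,
                 rng: np.random.Generator | None = None, init_slope: float = 0.25):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        fan_in = cin * stride**3
        self.w = self.add_param(
            "w", kaiming_uniform(rng, (cin, cout, stride, stride, stride), fan_in, init_slope)
        )
        bb = 1.0 / np.sqrt(fan_in)
        self.b = self.add_param("b", rng.uniform(-bb, bb, size=cout).astype(np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv_transpose3d(x, self.w, self.b, self.stride)


class BatchNorm3d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.add_param("gamma", np.ones(c, dtype=np.float32))
        self.beta = self.add_param("beta", np.zeros(c, dtype=np.float32))
        self.running_mean = self.add_buffer("running_mean", np.zeros(c))
        self.running_var = self.add_buffer("running_var", np.ones(c))

    def __call__(self, x: Tensor) -> Tensor:
        return core.batchnorm3d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Activation(Module):
    """'prelu' (learnable per-channel slope, init 0.25), 'leaky_relu'
    (fixed slope, default 0.5) or 'relu'."""

    def __init__(self, kind: str, channels: int, leaky_slope: float = 0.5,
                 prelu_init: float = 0.25):
        super().__init__()
        self.kind = kind
        self.leaky_slope = leaky_slope
        if kind == "prelu":
            self.a = self.add_param("a", np.full(channels, prelu_init, dtype=np.float32))
        elif kind not in ("leaky_relu", "relu"):
            raise ValueError(f"unknown activation {kind!r}")

    def __call__(self, x: Tensor) -> Tensor:
        if self.kind == "prelu":
            return core.prelu(x, self.a)
        slope = self.leaky_slope if self.kind == "leaky_relu" else 0.0
        return core.leaky_relu(x, slope)


class Dropout3d(Module):
    """Channelwise 3D dropout; the RNG is injected by the owning network so a
    single seed drives every stochastic layer."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        rng = self.rng if self.rng is not None else np.random.default_rng()
        return core.dropout3d(x, self.p, rng, self.training)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
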