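"""Layer/module abstractions over the autodiff ops."""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Module:
    """Base class with automatic parameter/child registration."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        elif isinstance(value, ModuleList):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, array: np.ndarray) -> None:
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            out[prefix + name] = np.asarray(b).copy()
        for name, child in self._children.items():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.ascontiguousarray(state[prefix + name], dtype=np.float32)
        for name, b in self._buffers.items():
            np.copyto(b, state[prefix + name])
        for name, child in self._children.items():
            child.load_state_dict(state, prefix + name + ".")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module) -> None:
        self._children[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self._list:
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True) -> "ModuleList":
        for m in self._list:
            m.train(mode)
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self._list):
            out.update(m.state_dict(f"{prefix}{i}."))
        return out

    def load_state_dict(self, state, prefix: str = "") -> None:
        for i, m in enumerate(self._list):
            m.load_state_dict(state, f"{prefix}{i}.")


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3d(Module):
    """3D convolution, "same" padding, Xavier-uniform initialization.

    Weights are stored channels-last as ``(k, k, k, in_ch, out_ch)`` to match
    the activation layout.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        k3 = kernel**3
        self.weight = Tensor(
            xavier_uniform((kernel, kernel, kernel, in_ch, out_ch), in_ch * k3, out_ch * k3, rng),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return F.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Dropout(Module):
    """Dropout drawing its masks from a generator shared across the network."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class DenseBlock(Module):
    """Densely connected block of BN-ReLU-Conv-Dropout units.

    Each convolution sees the channel concatenation of the block input and
    every previous unit's output; the block returns the concatenation of all
    of them, so the output has ``in_ch + n_convs * growth`` channels.
    """

    def __init__(self, in_ch: int, growth: int, n_convs: int, dropout_rate: float,
                 rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.norms = ModuleList()
        self.convs = ModuleList()
        self.drops = ModuleList()
        ch = in_ch
        for _ in range(n_convs):
            self.norms.append(BatchNorm3d(ch))
            self.convs.append(Conv3d(ch, growth, kernel, rng))
            self.drops.append(Dropout(dropout_rate, rng))
            ch += growth
        self.out_channels = ch

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for bn, conv, drop in zip(self.norms, self.convs, self.drops):
            h = feats[0] if len(feats) == 1 else F.concat_channels(feats)
            feats.append(drop(conv(F.relu(bn(h)))))
        return F.concat_channels(feats)
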