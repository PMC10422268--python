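"""Layer abstractions over the autodiff core: parameter registry, conv /
linear / batch-norm blocks and (de)serialization of weights."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter / submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for mod in self.modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -----------------------------------------------------
    def _buffers(self):
        """Override in subclasses carrying non-parameter state."""
        return {}

    def state_dict(self, prefix: str = ""):
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, arr in self._buffers().items():
            out[prefix + name] = np.array(arr, copy=True)
        for name, mod in self._modules.items():
            out.update(mod.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state, prefix: str = ""):
        for name, p in self._params.items():
            src = state[prefix + name]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {prefix + name}")
            p.data = np.array(src, dtype=np.float32, copy=True)
        for name in self._buffers():
            setattr(self, name, np.array(state[prefix + name], copy=True))
        for name, mod in self._modules.items():
            mod.load_state_dict(state, prefix + name + ".")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    """3x3 (or any odd k) same-padded convolution, He-normal init."""

    def __init__(self, cin: int, cout: int, k: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter(rng.normal(0.0, scale, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / cin)
        self.weight = Parameter(rng.normal(0.0, scale, (cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = T.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = T.batchnorm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return T.add(T.mul(x, Tensor(scale[None, :, None, None])),
                     Tensor(shift[None, :, None, None]))


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU; BN optional."""

    def __init__(self, cin, cout, k=3, batch_norm=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, bias=not batch_norm, rng=rng)
        self.bn = BatchNorm2d(cout) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return T.relu(x)
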