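"""Module system: parameter containers, state dicts, train/eval modes."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
           "Linear", "Sequential", "Identity"]


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    # -------------------------------------------------------------- registry
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n in self._buffers:
            yield prefix + n, getattr(self, n)
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # ----------------------------------------------------------------- modes
    def train(self, mode: bool = True) -> "Module":
        # modules flagged _always_eval (frozen blocks) stay in inference
        # mode regardless of the requested mode, as do their children
        eff = mode and not getattr(self, "_always_eval", False)
        self.training = eff
        for m in self._modules.values():
            m.train(eff)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def requires_grad_(self, flag: bool) -> "Module":
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        out.update({n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        missing = [k for k in list(own_p) + list(own_b) if k not in state]
        unexpected = [k for k in state if k not in own_p and k not in own_b]
        for k, v in state.items():
            tgt = own_p.get(k)
            if tgt is not None:
                if tgt.data.shape != v.shape:
                    raise ValueError(
                        f"shape mismatch for parameter '{k}': "
                        f"checkpoint {v.shape} vs model {tgt.data.shape}")
                tgt.data = np.asarray(v, dtype=np.float64).copy()
            elif k in own_b:
                if own_b[k].shape != v.shape:
                    raise ValueError(
                        f"shape mismatch for buffer '{k}': "
                        f"checkpoint {v.shape} vs model {own_b[k].shape}")
                own_b[k][...] = v
        if strict and (missing or unexpected):
            raise KeyError(f"state dict mismatch: missing={missing}, "
                           f"unexpected={unexpected}")
        return missing, unexpected

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel ** 3
        bound = float(np.sqrt(1.0 / fan_in))
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_ch, in_ch, kernel, kernel, kernel)))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.stride, self.padding)


class BatchNorm3d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool3d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool3d(x, self.kernel, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        bound = float(np.sqrt(1.0 / in_features))
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]
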