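"""Layer objects: parameter containers dispatching to the functional ops."""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import ShapeProxy, Tensor


class Module:
    """Base class: named parameter registry and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for c in self._children.values():
            c.train()
        return self

    def eval(self):
        self.training = False
        for c in self._children.values():
            c.eval()
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = arr


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, stem: bool = False):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("supported kernels: 1, 3")
        self.cin, self.cout, self.kernel, self.stem = cin, cout, kernel, stem
        self.padding = kernel // 2
        self.weight = _he_init(rng, (cout, cin, kernel, kernel, kernel), cin * kernel**3)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return F.conv3d(x, self.weight, self.bias, self.padding,
                        stem=self.stem and not isinstance(x, ShapeProxy))


class ConvTranspose3d2x(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he_init(rng, (cout, cin, 2, 2, 2), cin * 8)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return F.conv_transpose3d_2x(x, self.weight, self.bias)


def effective_groups(channels: int, norm_groups: int) -> int:
    """Largest divisor of ``channels`` not exceeding ``norm_groups``."""
    for g in range(min(norm_groups, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1


class GroupNorm(Module):
    def __init__(self, channels: int, norm_groups: int = 32, eps: float = 1e-5):
        super().__init__()
        self.groups = effective_groups(channels, norm_groups)
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x):
        return F.groupnorm(x, self.gamma, self.beta, self.groups, self.eps)


class Dropout(Module):
    """Block dropout; rate fixed at construction, disabled in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x):
        if not self.training or isinstance(x, ShapeProxy):
            return x
        return F.dropout(x, self.p, self.rng)


class MaxPool2x(Module):
    def __call__(self, x):
        return F.maxpool2(x)


class AvgPool2x(Module):
    def __call__(self, x):
        return F.avgpool2(x)


class UpsampleNearest2x(Module):
    def __call__(self, x):
        return F.upsample_nearest2(x)


class UpsampleTrilinear2x(Module):
    def __call__(self, x):
        return F.upsample_trilinear2(x)
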