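"""Layer/module abstractions over the autodiff tensors.

Modules own ``Parameter`` tensors (trained) and ``buffers`` (running
statistics, not trained). ``state_dict``/``load_state_dict`` flatten both
into name → ndarray maps for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, conv2d

__all__ = ["Parameter", "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- introspection ------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)

    def apply(self, fn):
        fn(self)
        for val in vars(self).values():
            if isinstance(val, Module):
                val.apply(fn)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.apply(fn)
        return self

    # -- mode ----------------------------------------------------------------
    def train(self):
        return self.apply(lambda m: setattr(m, "training", True))

    def eval(self):
        return self.apply(lambda m: setattr(m, "training", False))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, b in buffers.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != b.shape:
                raise ValueError(f"shape mismatch for buffer {name}")
            b[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """He-initialised 2-D convolution; bias off by default (BN follows)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_ch, in_ch, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x):
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding,
                      dilation=self.dilation)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return batch_norm(x, self.gamma, self.beta,
                          self.running_mean, self.running_var,
                          training=self.training,
                          momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()
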