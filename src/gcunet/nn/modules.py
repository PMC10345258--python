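"""Layer modules with explicit, seeded initialization.

Every module takes a ``numpy.random.Generator`` so two builds from the same
seed are parameter-identical. Weights use He-uniform init; modules whose
output feeds a residual sum can be zero-initialized so the surrounding block
starts as the identity.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, _make, as_tensor
from . import conv as F


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer." + name] = np.asarray(b).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != {k for k in state if not k.startswith("buffer.")}:
            raise ValueError("state dict parameter names do not match the model")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for qname, _ in self.named_buffers():
            key = "buffer." + qname
            if key in state:
                self._set_buffer(qname, state[key])

    def _set_buffer(self, qname: str, value: np.ndarray):
        parts = qname.split(".")
        mod = self
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]][...] = value

    def astype(self, dtype):
        """Cast all parameters and buffers in place (e.g. for gradient checks)."""
        for m in self.modules():
            for name, p in m._parameters.items():
                p.data = p.data.astype(dtype)
            for name in m._buffers:
                m._buffers[name] = m._buffers[name].astype(dtype)
                object.__setattr__(m, name, m._buffers[name])
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 stride=1, padding="same", bias=True, zero_init=False,
                 dtype=np.float32):
        super().__init__()
        k = kernel_size
        if padding == "same":
            if k % 2 == 0:
                raise ValueError(f"same-padding undefined for even kernel size {k}")
            padding = k // 2
        self.stride, self.padding = stride, padding
        fan_in = in_channels * k * k
        w = (np.zeros((out_channels, in_channels, k, k), dtype=dtype) if zero_init
             else _he_uniform(rng, (out_channels, in_channels, k, k), fan_in, dtype))
        self.weight = Tensor(w, requires_grad=True)
        if bias:
            bb = np.zeros(out_channels, dtype=dtype) if zero_init else _he_uniform(
                rng, (out_channels,), fan_in, dtype)
            self.bias = Tensor(bb, requires_grad=True)
        else:
            object.__setattr__(self, "bias", None)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 stride=2, padding=1, dtype=np.float32):
        super().__init__()
        k = kernel_size
        self.stride, self.padding = stride, padding
        fan_in = in_channels * k * k
        self.weight = Tensor(
            _he_uniform(rng, (in_channels, out_channels, k, k), fan_in, dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        gamma, beta = self.weight, self.bias
        if self.training:
            axes = (0, 2, 3)
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * invstd[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                    gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    x._accumulate(gi * (g - gsum / m - xhat * gx / m))
                else:
                    x._accumulate(gi * g)

        return _make(out, (x, gamma, beta), backward)


class LayerNorm(Module):
    """Normalizes over all non-batch axes (used on C/r x 1 x 1 vectors)."""

    def __init__(self, channels, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        gamma, beta = self.weight, self.bias
        axes = tuple(range(1, x.data.ndim))
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * invstd
        gshape = (1, -1) + (1,) * (x.data.ndim - 2)
        out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0,) + axes[1:]).reshape(gamma.data.shape))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0,) + axes[1:]).reshape(beta.data.shape))
            if x.requires_grad:
                m = np.prod([x.data.shape[a] for a in axes])
                gs = g * gamma.data.reshape(gshape)
                gsum = gs.sum(axis=axes, keepdims=True)
                gx = (gs * xhat).sum(axis=axes, keepdims=True)
                x._accumulate(invstd * (gs - gsum / m - xhat * gx / m))

        return _make(out, (x, gamma, beta), backward)
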