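"""Layer modules with parameter management, built on the autograd Tensor."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad and value._backward is None:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self):
        return sum(p.size for p in self.parameters())

    # checkpointing -------------------------------------------------------
    def state_dict(self):
        state = {name: p.data for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean
                state[f"{name}.running_var"] = m.running_var
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.ascontiguousarray(state[name], dtype=np.float32)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"], dtype=np.float32)
                m.running_var = np.asarray(state[f"{name}.running_var"], dtype=np.float32)

    def _named_modules(self, prefix=""):
        for name, m in self._modules.items():
            yield f"{prefix}{name}", m
            yield from m._named_modules(f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with He-normal weight initialization."""

    def __init__(self, in_channels, out_channels, kernel_size, padding=0,
                 bias=True, rng=None):
        super().__init__()
        if out_channels < 1 or in_channels < 1:
            raise ValueError("channel counts must be positive")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.kernel_size = kernel_size
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels

    def forward(self, x):
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training,
                             self.momentum, self.eps)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)
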