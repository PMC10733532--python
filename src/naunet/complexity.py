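"""Static accounting of parameters, activation memory, FLOPs and MAdds.

The profiler prices a model at a stated input size without executing the
full-resolution forward pass: the network is traced once at a 16x16 input
(batch 1), each recorded operation keeps its static descriptors, and because
every layer in these fully-convolutional networks has a per-spatial-position
cost, the trace is re-priced exactly at the requested size by scaling the
output H and W of every operation.

Per-layer cost rules (documented here in full; ``n`` = output elements):

==============  =======================================  =====================
layer           FLOPs                                    MAdds
==============  =======================================  =====================
convolution     n * (k^2 * c_in + 1 with bias)           n * (2 k^2 c_in - 1)
                                                         + n bias adds
batch norm      n                                        2 n
ReLU/sigmoid    n                                        n
2x2 max pool    4 n                                      3 n
upsample        0                                        0
add/multiply    n                                        n
concatenation   0                                        0
==============  =======================================  =====================

Memory is the forward activation storage (4 bytes per value, batch 1, every
operation output counted once) plus parameter storage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import profile as nnprofile

_BASE = 16  # trace resolution; inputs are divisible by 16 so scaling is exact


@dataclass
class ComplexityReport:
    """Cost accounting for one model at one input size."""

    n_params: int
    total_memory: int       # bytes
    flops: int
    madds: int
    input_dims: tuple       # (channels, height, width)

    @property
    def params_millions(self):
        return self.n_params / 1e6

    @property
    def memory_gb(self):
        return self.total_memory / 2**30

    @property
    def flops_g(self):
        return self.flops / 1e9

    @property
    def madds_g(self):
        return self.madds / 1e9

    def as_row(self, name="model"):
        return {"model": name,
                "params_millions": round(self.params_millions, 2),
                "memory_gb": round(self.memory_gb, 2),
                "flops_g": round(self.flops_g, 2),
                "madds_g": round(self.madds_g, 2)}


def count_params(model) -> int:
    """Total learnable scalars, by enumerating every parameter array."""
    return model.num_parameters()


def _trace(model, in_channels):
    was_training = model.training
    model.eval()
    x = np.zeros((1, in_channels, _BASE, _BASE), dtype=np.float32)
    with nnprofile.record() as rec:
        model(x)
    model.train(was_training)
    return rec.entries


def _price(entries, sh, sw):
    flops = madds = mem = 0
    for e in entries:
        kind = e["kind"]
        if kind == "conv":
            n = e["c_out"] * (e["h_out"] * sh) * (e["w_out"] * sw)
            k2c = e["k"] * e["k"] * e["c_in"]
            flops += n * (k2c + (1 if e["bias"] else 0))
            madds += n * (2 * k2c - 1) + (n if e["bias"] else 0)
            mem += n
        elif kind == "bn":
            n = e["c"] * (e["h"] * sh) * (e["w"] * sw)
            flops += n
            madds += 2 * n
            mem += n
        elif kind == "act":
            n = int(np.prod(e["shape"][:-2])) * (e["shape"][-2] * sh) * (e["shape"][-1] * sw)
            flops += n
            madds += n
            mem += n
        elif kind == "pool":
            n = e["c"] * (e["h_out"] * sh) * (e["w_out"] * sw)
            flops += 4 * n
            madds += 3 * n
            mem += n
        elif kind == "upsample":
            mem += e["c"] * (e["h_out"] * sh) * (e["w_out"] * sw)
        elif kind in ("add", "mul"):
            n = int(np.prod(e["shape"][:-2])) * (e["shape"][-2] * sh) * (e["shape"][-1] * sw)
            flops += n
            madds += n
            mem += n
        elif kind == "concat":
            mem += int(np.prod(e["shape"][:-2])) * (e["shape"][-2] * sh) * (e["shape"][-1] * sw)
        else:
            raise ValueError(f"complexity: no cost rule for layer kind {kind!r}")
    return flops, madds, mem


def count_flops(model, input_dims=(3, 576, 576)) -> ComplexityReport:
    """Price ``model`` at ``input_dims`` = (channels, H, W); H, W divisible by 16."""
    c, h, w = input_dims
    if h % _BASE or w % _BASE:
        raise ValueError(f"input spatial dims ({h}, {w}) must be divisible by {_BASE}")
    entries = _trace(model, c)
    flops, madds, acts = _price(entries, h // _BASE, w // _BASE)
    n_params = count_params(model)
    mem = 4 * (acts + c * h * w + n_params)  # activations + input + weights
    return ComplexityReport(n_params=n_params, total_memory=mem, flops=flops,
                            madds=madds, input_dims=tuple(input_dims))


def memory_estimate(model, input_dims=(3, 576, 576)) -> int:
    """Forward activation + parameter storage in bytes (batch 1, float32)."""
    return count_flops(model, input_dims).total_memory


def complexity_table(models: dict, input_dims=(3, 576, 576)) -> pd.DataFrame:
    """One row per named model, in the published table's column layout."""
    rows = [count_flops(m, input_dims).as_row(name) for name, m in models.items()]
    return pd.DataFrame(rows)
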