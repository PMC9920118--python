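"""Layer objects: parameter containers around the functional core ops."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor

__all__ = ["Module", "Conv1d", "ConvTranspose1d", "BatchNorm1d", "Dense"]


class Module:
    """Base class: recursively exposes parameters and mutable state."""

    def parameters(self):
        """Yield (qualified_name, Tensor) for every trainable parameter."""
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val
            elif isinstance(val, Module):
                for sub, p in val.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{i}.{sub}", p

    def n_parameters(self) -> int:
        return sum(p.data.size for _, p in self.parameters())

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict:
        """All arrays needed to restore the module: parameters, BN statistics
        and (for models) the rate-output affine de-standardisation."""
        out = {name: p.data for name, p in self.parameters()}
        for name, st in self._stats():
            out[name] = st
        rn = getattr(self, "rr_norm", None)
        if rn is not None:
            out["rr_norm.offset"] = rn["offset"]
            out["rr_norm.scale"] = rn["scale"]
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        params = dict(self.parameters())
        for name, arr in arrays.items():
            if name in params:
                params[name].data = np.array(arr, dtype=np.float64)
        stats = dict(self._stats())
        for name, arr in arrays.items():
            if name in stats:
                stats[name][...] = arr
        rn = getattr(self, "rr_norm", None)
        if rn is not None:
            if "rr_norm.offset" in arrays:
                rn["offset"] = np.array(arrays["rr_norm.offset"])
            if "rr_norm.scale" in arrays:
                rn["scale"] = np.array(arrays["rr_norm.scale"])

    def _stats(self):
        for name, val in vars(self).items():
            if isinstance(val, BatchNorm1d):
                yield f"{name}.running_mean", val.running["mean"]
                yield f"{name}.running_var", val.running["var"]
            elif isinstance(val, Module):
                for sub, st in val._stats():
                    yield f"{name}.{sub}", st
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, BatchNorm1d):
                        yield f"{name}.{i}.running_mean", item.running["mean"]
                        yield f"{name}.{i}.running_var", item.running["var"]
                    elif isinstance(item, Module):
                        for sub, st in item._stats():
                            yield f"{name}.{i}.{sub}", st


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape),
                  requires_grad=True)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.w = _he(rng, (cout, cin, k), cin * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv1d(x, self.w, self.b, stride=self.stride)


class ConvTranspose1d(Module):
    """Transposed 1-D convolution realised as zero-stuffing (stride 2) or
    identity resampling (stride 1) followed by a 'same' convolution, so each
    stride-2 level exactly doubles the length with no off-by-one crops."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.w = _he(rng, (cout, cin, k), cin * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.stride == 2:
            x = core.zero_stuff2(x)
        return core.conv1d(x, self.w, self.b, stride=1)


class BatchNorm1d(Module):
    def __init__(self, c: int, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.momentum = momentum
        self.running = {"mean": np.zeros(c), "var": np.ones(c)}

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return core.batch_norm(x, self.gamma, self.beta, self.running,
                               training, self.momentum)


class Dense(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = _he(rng, (fin, fout), fin)
        self.b = Tensor(np.zeros(fout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return core.dense(x, self.w, self.b)
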