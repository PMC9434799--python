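"""Layer objects: convolution, transposed convolution, batch norm, linear.

Layers own :class:`~mmunet.autodiff.Parameter` objects and a ``train`` flag
(batch normalization behaves differently in training and evaluation mode).
Weight initialization is Kaiming-style fan-in scaling, drawn from a
caller-supplied :class:`numpy.random.Generator` so that construction is
fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

DTYPE = np.float32


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_train(self, mode: bool) -> None:
        for attr in self.__dict__.values():
            if isinstance(attr, Module):
                attr.set_train(mode)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.set_train(mode)
        if hasattr(self, "training"):
            self.training = mode

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same' padding chosen by the caller."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        *,
        pad: int,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator,
        name: str = "conv",
    ):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.pad, self.dilation = kernel, pad, dilation
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            _kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in), f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE), f"{name}.bias") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch} input channels, got {x.shape[1]}"
            )
        return ad.conv2d(x, self.weight, self.bias, self.pad, self.dilation)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (the decoder upsampler)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        *,
        bias: bool = True,
        rng: np.random.Generator,
        name: str = "deconv",
    ):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_kaiming(rng, (in_ch, out_ch, 2, 2), in_ch * 4), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE), f"{name}.bias") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        return ad.conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode normalizes with batch statistics (differentiably) and
    updates running estimates; evaluation mode uses the running estimates,
    so inference is deterministic and batch-independent.
    """

    def __init__(self, ch: int, *, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.ch = ch
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(ch, dtype=DTYPE), f"{name}.gamma")
        self.beta = Parameter(np.zeros(ch, dtype=DTYPE), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, self.ch, 1, 1)
        b = self.beta.reshape(1, self.ch, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbias * var.data.reshape(-1)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            inv = (1.0 / np.sqrt(self.running_var + self.eps))[None, :, None, None]
            xhat = (x - ad.Tensor(mu)) * ad.Tensor(inv)
        return xhat * g + b


class Linear(Module):
    def __init__(
        self,
        in_f: int,
        out_f: int,
        *,
        bias: bool = True,
        rng: np.random.Generator,
        name: str = "linear",
    ):
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(_kaiming(rng, (in_f, out_f), in_f), f"{name}.weight")
        self.bias = Parameter(np.zeros(out_f, dtype=DTYPE), f"{name}.bias") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x.matmul(self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


def state_dict(module: Module) -> dict[str, np.ndarray]:
    """Flat name->array mapping of parameters and batch-norm running stats."""
    out: dict[str, np.ndarray] = {}
    for i, p in enumerate(module.parameters()):
        out[f"p{i:04d}:{p.name}"] = p.data
    for j, bn in enumerate(_batchnorms(module)):
        out[f"rs{j:04d}:mean"] = bn.running_mean
        out[f"rs{j:04d}:var"] = bn.running_var
    return out


def load_state_dict(module: Module, state: dict[str, np.ndarray]) -> None:
    params = module.parameters()
    bns = _batchnorms(module)
    for key, arr in state.items():
        kind, _, _ = key.partition(":")
        if kind.startswith("rs"):
            bn = bns[int(kind[2:])]
            if key.endswith(":mean"):
                bn.running_mean = arr.astype(DTYPE)
            else:
                bn.running_var = arr.astype(DTYPE)
        else:
            p = params[int(kind[1:])]
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {arr.shape}")
            p.data = arr.astype(DTYPE)


def _batchnorms(module: Module) -> list[BatchNorm2d]:
    found: list[BatchNorm2d] = []
    for attr in module.__dict__.values():
        if isinstance(attr, BatchNorm2d):
            found.append(attr)
        elif isinstance(attr, Module):
            found.extend(_batchnorms(attr))
        elif isinstance(attr, (list, tuple)):
            for item in attr:
                if isinstance(item, Module):
                    found.extend(_batchnorms(item))
    return found
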