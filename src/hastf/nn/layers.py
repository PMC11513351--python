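"""Trainable layers on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["Module", "Linear", "Conv2d", "LayerNorm"]


class Module:
    """Minimal parameter container: children and Tensor attributes are
    discovered by introspection, as in the usual deep-learning idiom."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match parameter count")
        for i, p in enumerate(params):
            p.data = np.asarray(state[str(i)], dtype=np.float64).reshape(p.data.shape)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Linear(Module):
    """Affine map y = x W^T + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_kaiming(rng, (out_dim, in_dim), in_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class Conv2d(Module):
    """3x3 (or 1x1) convolution, stride 1, configurable padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        padding: int,
        rng: np.random.Generator,
    ):
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class LayerNorm(Module):
    """Normalize the trailing dimension to zero mean / unit variance, then
    apply a learned elementwise gain and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta
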