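"""Spatial Attention Feature Extractor (SAFE).

Two stages act on each 1-s patch's band x 9 x 9 grid:

1. **U-shaped continuous convolution fusion (UCCF)** — five stride-1
   convolutions whose spatial size never changes (3x3 kernels with
   padding 1; the last layer is 1x1 with padding 0).  The first two
   layers expand the feature-map count, the last three contract it, and
   skip connections concatenate layer 1's output into layer 5's input and
   layer 2's output into layer 4's input, so fine-grained shallow
   structure survives to the deep layers.

2. **Parameter-free spatial attention** — each position t of a feature
   map is scored by the minimum of an energy function measuring how
   linearly separable t is from the other M-1 positions (the
   spatial-inhibition rationale: units that stand out from their
   neighborhood matter more).  With targets y_t = +1 for t and y_o = -1
   for the others and an L2 penalty lambda on the slope, the energy

       e_t(w, b) = (1 - (w t + b))^2
                   + (1/(M-1)) * sum_i (-1 - (w x_i + b))^2 + lambda w^2

   has the closed-form minimizer

       w_t = -2 (t - u_t) / ((t - u_t)^2 + 2 sigma_t^2 + 2 lambda)
       b_t = -(t + u_t) w_t / 2

   where u_t and sigma_t^2 are the mean and variance of the other M-1
   positions, and the minimum value

       e*_t = 4 (sigma_t^2 + lambda) / ((t - u_t)^2 + 2 sigma_t^2 + 2 lambda).

   Importance is 1/e*; the refined map is sigmoid(1/e*) (.) X, so the
   module carries exactly zero trainable parameters and never flips a
   feature's sign.

The refined maps are max-pooled (2x2, stride 2), flattened and affinely
projected to the embedding width d; one embedding per (window, patch)
feeds the temporal encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Conv2d, Linear, Tensor, concat, maxpool2d

__all__ = [
    "SAParams",
    "AttentionMap",
    "UCCFConfig",
    "simam_energy",
    "spatial_attention",
    "attention_refine",
    "UCCF",
    "SAFE",
]


@dataclass(frozen=True)
class SAParams:
    """Constants of the energy-based attention.

    lam is the L2 regularization constant lambda (the only tunable);
    statistics_mode 'leave_one_out' uses the mean/variance of the other
    M-1 positions (the defining form), 'shared' uses all M positions as a
    faster approximation.
    """

    lam: float = 1e-4
    y_t: float = 1.0
    y_o: float = -1.0
    statistics_mode: str = "leave_one_out"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.statistics_mode not in ("leave_one_out", "shared"):
            raise ValueError(f"unknown statistics_mode {self.statistics_mode!r}")


@dataclass
class AttentionMap:
    """Per-position energies and weights, retained for inspection."""

    energies: np.ndarray  # minimal energy e* per position
    weights: np.ndarray  # sigmoid(1/e*), strictly in (0, 1)
    mean: np.ndarray  # u_t per position
    variance: np.ndarray  # sigma_t^2 per position


def _loo_stats(x: np.ndarray, lam: float, mode: str):
    """Per-position mean/variance of the other positions of each 2D map.

    x has shape (..., H, W); statistics are over the trailing two axes.
    Leave-one-out values follow from the full-map sums: with S = sum x,
    S2 = sum x^2 and M positions, u_t = (S - t)/(M-1) and
    sigma_t^2 = (S2 - t^2)/(M-1) - u_t^2 (exact algebra, no loops).
    """
    M = x.shape[-1] * x.shape[-2]
    if M < 2:
        raise ValueError("attention needs at least 2 spatial positions")
    S = x.sum(axis=(-2, -1), keepdims=True)
    S2 = (x * x).sum(axis=(-2, -1), keepdims=True)
    if mode == "leave_one_out":
        u = (S - x) / (M - 1)
        var = np.maximum((S2 - x * x) / (M - 1) - u * u, 0.0)
    else:
        u = np.broadcast_to(S / M, x.shape)
        var = np.broadcast_to(np.maximum(S2 / M - (S / M) ** 2, 0.0), x.shape)
    return u, var


def simam_energy(
    feature_map: np.ndarray, pos: tuple[int, int], params: SAParams = SAParams()
) -> float:
    """Minimal energy e* of the position ``pos`` of one 2D feature map."""
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.size < 2:
        raise ValueError("feature map needs at least 2 positions")
    u, var = _loo_stats(fm, params.lam, params.statistics_mode)
    t = fm[pos]
    d2 = (t - u[pos]) ** 2
    return float(4.0 * (var[pos] + params.lam) / (d2 + 2.0 * var[pos] + 2.0 * params.lam))


def spatial_attention(
    features: np.ndarray, params: SAParams = SAParams()
) -> tuple[np.ndarray, AttentionMap]:
    """Refine a stack of 2D maps: output = sigmoid(1/e*) (.) input.

    features: (..., H, W). Contains no trainable parameters; weights are
    returned for inspection alongside the refined features.
    """
    x = np.asarray(features, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in attention input")
    u, var = _loo_stats(x, params.lam, params.statistics_mode)
    d2 = (x - u) ** 2
    e_star = 4.0 * (var + params.lam) / (d2 + 2.0 * var + 2.0 * params.lam)
    weights = 1.0 / (1.0 + np.exp(-1.0 / e_star))
    return weights * x, AttentionMap(energies=e_star, weights=weights, mean=u, variance=var)


def attention_refine(x: Tensor, params: SAParams = SAParams()) -> Tensor:
    """Differentiable spatial attention on a (N, C, H, W) tensor.

    Same closed form as :func:`spatial_attention`, expressed in autodiff
    primitives so gradients flow through both the weights and the values.
    """
    H, W = x.shape[-2], x.shape[-1]
    M = H * W
    S = x.sum(axis=(2, 3), keepdims=True)
    S2 = (x * x).sum(axis=(2, 3), keepdims=True)
    if params.statistics_mode == "leave_one_out":
        u = (S - x) * (1.0 / (M - 1))
        var = (S2 - x * x) * (1.0 / (M - 1)) - u * u
    else:
        u = S * (1.0 / M)
        var = S2 * (1.0 / M) - u * u
    d = x - u
    e_star = (var + params.lam) * 4.0 / (d * d + var * 2.0 + 2.0 * params.lam)
    weights = (Tensor([1.0]) / e_star).sigmoid()
    return weights * x


@dataclass(frozen=True)
class UCCFConfig:
    """Five-layer U-shaped convolution stack over 9x9 band maps.

    filters are the per-layer feature-map counts; kernel/padding of the
    first four layers are 3/1 and of the last 1/0, so the 9x9 spatial
    size is preserved throughout.  Skip pairs: layer 2 -> input of layer
    4, layer 1 -> input of layer 5, by channel concatenation.
    """

    in_bands: int = 5
    filters: tuple[int, int, int, int, int] = (64, 128, 128, 64, 32)
    use_skip: bool = True

    @property
    def layer4_in(self) -> int:
        return self.filters[2] + (self.filters[1] if self.use_skip else 0)

    @property
    def layer5_in(self) -> int:
        return self.filters[3] + (self.filters[0] if self.use_skip else 0)


class UCCF(Module):
    """U-shaped continuous convolution fusion network."""

    def __init__(self, cfg: UCCFConfig, rng: np.random.Generator):
        f = cfg.filters
        self.cfg = cfg
        self.conv1 = Conv2d(cfg.in_bands, f[0], 3, 1, rng)
        self.conv2 = Conv2d(f[0], f[1], 3, 1, rng)
        self.conv3 = Conv2d(f[1], f[2], 3, 1, rng)
        self.conv4 = Conv2d(cfg.layer4_in, f[3], 3, 1, rng)
        self.conv5 = Conv2d(cfg.layer5_in, f[4], 1, 0, rng)

    def __call__(self, x: Tensor) -> Tensor:
        y1 = self.conv1(x).relu()
        y2 = self.conv2(y1).relu()
        y3 = self.conv3(y2).relu()
        in4 = concat([y3, y2], axis=1) if self.cfg.use_skip else y3
        y4 = self.conv4(in4).relu()
        in5 = concat([y4, y1], axis=1) if self.cfg.use_skip else y4
        return self.conv5(in5).relu()


class SAFE(Module):
    """UCCF -> spatial attention -> 2x2 max pool -> flatten -> project to d.

    use_uccf / use_attention switch the corresponding stage to identity
    (the ablation variants); with use_uccf False the attention acts
    directly on the input band maps.
    """

    def __init__(
        self,
        cfg: UCCFConfig,
        embed_dim: int,
        rng: np.random.Generator,
        sa_params: SAParams = SAParams(),
        use_uccf: bool = True,
        use_attention: bool = True,
        pool: int = 2,
    ):
        self.cfg = cfg
        self.sa_params = sa_params
        self.use_uccf = use_uccf
        self.use_attention = use_attention
        self.pool = pool
        self.uccf = UCCF(cfg, rng) if use_uccf else None
        maps = cfg.filters[4] if use_uccf else cfg.in_bands
        side = 9 // pool
        self.proj = Linear(maps * side * side, embed_dim, rng)
        self.embed_dim = embed_dim

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N patches, bands, 9, 9) -> (N patches, d)."""
        feats = self.uccf(x) if self.use_uccf else x
        if self.use_attention:
            feats = attention_refine(feats, self.sa_params)
        pooled = maxpool2d(feats, self.pool)
        N = pooled.shape[0]
        flat = pooled.reshape(N, -1)
        return self.proj(flat)
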