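"""Temporal Attention Feature Extractor (TAFE).

The T per-patch spatial embeddings of a window form a token sequence; a
learnable class token is prepended (BERT-style) and a learnable positional
encoding is added.  The sequence then passes through a stack of
post-norm transformer encoder layers:

    Z_A = LayerNorm(MSA(Z) + Z)
    Z'  = LayerNorm(FFN(Z_A) + Z_A),   FFN = Linear -> GELU -> Linear

where MSA is multi-head scaled dot-product self-attention: per head h,
Q_h, K_h, V_h are affine maps of Z, attention is
softmax(Q_h K_h^T / sqrt(d_k)) V_h, heads are concatenated and mapped
back to the model width.  After the last layer the class token's state is
affinely mapped to the class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .nn import LayerNorm, Linear, Module, Tensor

__all__ = ["EncoderConfig", "MultiHeadAttention", "EncoderLayer", "TAFE"]


@dataclass(frozen=True)
class EncoderConfig:
    """Transformer encoder hyperparameters.

    Defaults follow the reference configuration: 6 layers, 8 heads, model
    width d = 256 with QKV width equal to d, and an FFN hidden width of
    128 (an inverted bottleneck; both widths are configurable).
    token_init 'truncated_normal' draws class-token and positional
    encoding entries from a standard normal truncated to [0, 1];
    'normal' uses plain standard-normal draws.
    """

    n_layers: int = 6
    n_heads: int = 8
    model_dim: int = 256
    qkv_dim: int = 256
    ffn_dim: int = 128
    token_init: str = "truncated_normal"

    def __post_init__(self) -> None:
        if self.qkv_dim % self.n_heads != 0:
            raise ValueError(
                f"qkv_dim {self.qkv_dim} not divisible by {self.n_heads} heads"
            )

    @property
    def head_dim(self) -> int:
        return self.qkv_dim // self.n_heads


class MultiHeadAttention(Module):
    """Batched multi-head scaled dot-product self-attention.

    Scores are scaled by 1/sqrt(d_k) exactly once before the row softmax;
    every attention row therefore lies on the probability simplex.  The
    most recent per-head attention matrices are kept on
    ``last_attention`` (shape (N, heads, T+1, T+1)) for inspection.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, dq = cfg.model_dim, cfg.qkv_dim
        self.wq = Linear(d, dq, rng)
        self.wk = Linear(d, dq, rng)
        self.wv = Linear(d, dq, rng)
        self.wo = Linear(dq, d, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, z: Tensor) -> Tensor:
        """z: (N, L, d) -> (N, L, d)."""
        N, L, _ = z.shape
        H, dk = self.cfg.n_heads, self.cfg.head_dim
        q = self.wq(z).reshape(N, L, H, dk).transpose(0, 2, 1, 3)
        k = self.wk(z).reshape(N, L, H, dk).transpose(0, 2, 1, 3)
        v = self.wv(z).reshape(N, L, H, dk).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data.copy()
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(N, L, H * dk)
        return self.wo(mixed)


class EncoderLayer(Module):
    """Post-norm transformer block: attention and FFN sublayers with
    residual connections and LayerNorm after each."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.msa = MultiHeadAttention(cfg, rng)
        self.norm1 = LayerNorm(cfg.model_dim)
        self.norm2 = LayerNorm(cfg.model_dim)
        self.ffn1 = Linear(cfg.model_dim, cfg.ffn_dim, rng)
        self.ffn2 = Linear(cfg.ffn_dim, cfg.model_dim, rng)

    def __call__(self, z: Tensor) -> Tensor:
        za = self.norm1(self.msa(z) + z)
        ff = self.ffn2(self.ffn1(za).gelu())
        return self.norm2(ff + za)


def _token_init(rng: np.random.Generator, shape: tuple[int, ...], mode: str) -> np.ndarray:
    if mode == "truncated_normal":
        return truncnorm.rvs(0.0, 1.0, size=shape, random_state=rng)
    if mode == "normal":
        return rng.standard_normal(shape)
    raise ValueError(f"unknown token_init {mode!r}")


class TAFE(Module):
    """Class-token transformer encoder with classification head.

    Consumes (N windows, T, d) patch embeddings; prepends the class token
    (sequence length becomes T+1 with the class token at index 0), adds
    the learnable positional encoding, applies the encoder stack and maps
    the final class-token state to n_classes logits.
    """

    def __init__(
        self,
        cfg: EncoderConfig,
        seq_len_t: int,
        n_classes: int,
        rng: np.random.Generator,
    ):
        self.cfg = cfg
        self.seq_len_t = seq_len_t
        d = cfg.model_dim
        self.class_token = Tensor(
            _token_init(rng, (1, 1, d), cfg.token_init), requires_grad=True
        )
        self.pos_encoding = Tensor(
            _token_init(rng, (1, seq_len_t + 1, d), cfg.token_init), requires_grad=True
        )
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]
        self.head = Linear(d, n_classes, rng)

    def encode(self, features: Tensor) -> Tensor:
        """(N, T, d) -> (N, T+1, d) final-layer token states."""
        N, T, d = features.shape
        if T != self.seq_len_t:
            raise ValueError(f"expected {self.seq_len_t} patch tokens, got {T}")
        cls = self.class_token + Tensor(np.zeros((N, 1, d)))  # broadcast copy
        from .nn import concat

        z = concat([cls, features], axis=1) + self.pos_encoding
        for layer in self.layers:
            z = layer(z)
        return z

    def __call__(self, features: Tensor) -> Tensor:
        """(N, T, d) -> (N, n_classes) logits from the class token."""
        z = self.encode(features)
        return self.head(z[:, 0, :])
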