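"""The full hybrid attention spatio-temporal network and its ablations.

A classification sample is one window: T per-second patches, each a
band x 9 x 9 DE grid.  Every patch passes through the spatial extractor
(SAFE) to a d-dimensional embedding; the T embeddings form the token
sequence of the temporal extractor (TAFE), whose class-token state yields
the logits.

Ablation variants (structural edits, trained with identical folds/seeds):

========  ===========================================================
All       the full network
Wo-Sc     UCCF without the two skip concatenations
Wo-SA     spatial attention replaced by identity
Wo-UCCF   convolutions bypassed: attention + pooling act on the raw
          band maps, then projection to d
Wo-SAFE   whole spatial stage bypassed: each patch grid is flattened
          and affinely projected to d, straight into TAFE
Wo-TAFE   temporal stage bypassed: patch embeddings are averaged over
          T and classified by an affine head
========  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Linear, Module, Tensor
from .safe import SAFE, SAParams, UCCFConfig
from .tafe import TAFE, EncoderConfig

__all__ = ["HASTFConfig", "HASTFNetwork", "VARIANTS", "desk_scale_config", "reference_scale_config"]

VARIANTS = ("All", "Wo-Sc", "Wo-SA", "Wo-UCCF", "Wo-SAFE", "Wo-TAFE")


@dataclass(frozen=True)
class HASTFConfig:
    """Architecture hyperparameters of the full network."""

    uccf: UCCFConfig = field(default_factory=UCCFConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    sa: SAParams = field(default_factory=SAParams)
    embed_dim: int = 256
    seq_len_t: int = 8
    n_classes: int = 2


def reference_scale_config(seq_len_t: int = 8, n_classes: int = 2) -> HASTFConfig:
    """The reference configuration: 6 encoder layers, 8 heads, d = 256."""
    return HASTFConfig(seq_len_t=seq_len_t, n_classes=n_classes)


def desk_scale_config(seq_len_t: int = 8, n_classes: int = 2) -> HASTFConfig:
    """A reduced configuration for CPU-scale experiments and tests:
    filter counts (8,16,16,8,8), d = 32, 2 encoder layers, 4 heads."""
    return HASTFConfig(
        uccf=UCCFConfig(filters=(8, 16, 16, 8, 8)),
        encoder=EncoderConfig(n_layers=2, n_heads=4, model_dim=32, qkv_dim=32, ffn_dim=32),
        embed_dim=32,
        seq_len_t=seq_len_t,
        n_classes=n_classes,
    )


class HASTFNetwork(Module):
    """Spatial + temporal extractors wired per the chosen ablation variant."""

    def __init__(self, cfg: HASTFConfig, rng: np.random.Generator, variant: str = "All"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        d = cfg.embed_dim

        if variant == "Wo-SAFE":
            self.safe = None
            self.patch_proj = Linear(cfg.uccf.in_bands * 81, d, rng)
        else:
            uccf_cfg = cfg.uccf
            if variant == "Wo-Sc":
                uccf_cfg = replace(uccf_cfg, use_skip=False)
            self.safe = SAFE(
                uccf_cfg,
                d,
                rng,
                sa_params=cfg.sa,
                use_uccf=variant != "Wo-UCCF",
                use_attention=variant != "Wo-SA",
            )
            self.patch_proj = None

        if variant == "Wo-TAFE":
            self.tafe = None
            self.avg_head = Linear(d, cfg.n_classes, rng)
        else:
            self.tafe = TAFE(cfg.encoder, cfg.seq_len_t, cfg.n_classes, rng)
            self.avg_head = None

    def embed_patches(self, x: Tensor) -> Tensor:
        """(N, T, B, 9, 9) -> (N, T, d) per-patch spatial embeddings."""
        N, T = x.shape[0], x.shape[1]
        flat = x.reshape(N * T, *x.shape[2:])
        if self.safe is not None:
            emb = self.safe(flat)
        else:
            emb = self.patch_proj(flat.reshape(N * T, -1))
        return emb.reshape(N, T, self.cfg.embed_dim)

    def __call__(self, x: Tensor) -> Tensor:
        """(N windows, T, B, 9, 9) -> (N, n_classes) logits."""
        tokens = self.embed_patches(x)
        if self.tafe is not None:
            return self.tafe(tokens)
        pooled = tokens.mean(axis=1)
        return self.avg_head(pooled)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under row-softmax."""
    n = logits.shape[0]
    probs = logits.softmax(axis=-1)
    picked = probs[np.arange(n), np.asarray(labels)]
    return -(picked.log().mean())
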