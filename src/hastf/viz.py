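"""Attention feature-map extraction and topographic rendering.

The parameter-free spatial attention assigns every grid position a weight
in (0, 1); averaging those weights over feature maps and patches gives a
9x9 scalp map of where the network attends.  Cells with no electrode are
masked.  Two visualized quantities are supported: the attention weights
themselves (default) and the magnitude of the attended activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .montage import GridTensor, MappingError, MontageGrid
from .nn import Tensor
from .safe import SAParams, spatial_attention

__all__ = ["FeatureMapGrid", "extract_attention_map", "average_by_class", "render_topomap"]


@dataclass
class FeatureMapGrid:
    """A 9x9 scalp map of mean attention weight (or activation magnitude)."""

    values: np.ndarray  # (9, 9); unoccupied cells are np.nan
    montage: MontageGrid
    quantity: str = "attention_weight"
    class_label: object = None
    subject_id: str = ""
    normalization: str = "none"

    def normalized(self) -> "FeatureMapGrid":
        """Min-max scale the occupied cells to [0, 1]."""
        vals = self.values.copy()
        occ = ~np.isnan(vals)
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        if hi > lo:
            vals[occ] = (vals[occ] - lo) / (hi - lo)
        else:
            vals[occ] = 0.0
        return FeatureMapGrid(
            values=vals,
            montage=self.montage,
            quantity=self.quantity,
            class_label=self.class_label,
            subject_id=self.subject_id,
            normalization="minmax",
        )

    def channel_means(self, channels: list[str]) -> float:
        """Mean map value over the named channels."""
        vals = [self.values[self.montage.placement[ch]] for ch in channels]
        return float(np.mean(vals))


def extract_attention_map(
    model,
    grids: GridTensor,
    window_indices: np.ndarray | None = None,
    stage: str = "input",
    quantity: str = "attention_weight",
    sa_params: SAParams = SAParams(),
) -> FeatureMapGrid:
    """Average spatial-attention weights of selected windows onto the grid.

    stage 'input' computes attention directly on the DE band maps (the
    convolution-free configuration, montage-aligned by construction);
    stage 'features' runs the model's convolution stack first and
    averages over its feature maps.  ``model`` may be None for stage
    'input'.  quantity 'attention_weight' averages sigmoid(1/e*);
    'activation' averages |weight * value|.
    """
    x = grids.values
    if window_indices is not None:
        x = x[np.asarray(window_indices)]
    n, T, B = x.shape[:3]
    flat = x.reshape(n * T, B, 9, 9)
    mask = grids.montage.occupancy_mask()

    if stage == "input":
        # On raw band maps the population of peers is the electrode set:
        # energy statistics run over the occupied cells only (M = channel
        # count), so fill values in electrode-free cells never contribute.
        occ_vals = flat[..., mask]  # (nT, B, C)
        refined, attn = spatial_attention(occ_vals[..., None, :], sa_params)
        per_channel = (
            attn.weights if quantity == "attention_weight" else np.abs(refined)
        )[..., 0, :].mean(axis=(0, 1))
        if quantity not in ("attention_weight", "activation"):
            raise ValueError(f"unknown quantity {quantity!r}")
        cell_vals = np.zeros((9, 9))
        cell_vals[mask] = per_channel
    elif stage == "features":
        if model is None or getattr(model, "safe", None) is None or model.safe.uccf is None:
            raise MappingError("stage='features' needs a model with a convolution stack")
        maps = model.safe.uccf(Tensor(flat)).data
        refined, attn = spatial_attention(maps, sa_params)
        if quantity == "attention_weight":
            cell_vals = attn.weights.mean(axis=(0, 1))
        elif quantity == "activation":
            cell_vals = np.abs(refined).mean(axis=(0, 1))
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
    else:
        raise ValueError(f"unknown stage {stage!r}")

    out = np.where(mask, cell_vals, np.nan)
    return FeatureMapGrid(
        values=out,
        montage=grids.montage,
        quantity=quantity,
        subject_id=grids.subject_id,
    )


def average_by_class(
    maps: list[FeatureMapGrid], labels: list
) -> dict[object, FeatureMapGrid]:
    """Cellwise mean map per class.

    Each input map is weighted equally (so per-subject maps average
    subjects equally); raises if any requested class has no maps.
    """
    if len(maps) != len(labels):
        raise ValueError("one label per map required")
    if not maps:
        raise ValueError("no maps given")
    out: dict[object, FeatureMapGrid] = {}
    for cls in sorted(set(labels), key=repr):
        stack = [m.values for m, lab in zip(maps, labels) if lab == cls]
        if not stack:
            raise ValueError(f"class {cls!r} has no maps")
        out[cls] = FeatureMapGrid(
            values=np.mean(stack, axis=0),
            montage=maps[0].montage,
            quantity=maps[0].quantity,
            class_label=cls,
        )
    return out


def render_topomap(fmap: FeatureMapGrid, out_path, cmap: str = "viridis", dpi: int = 100):
    """Write a raster image of the scalp map.

    Masked (electrode-free) cells are transparent; channel labels are
    overlaid; deterministic given identical inputs and settings.
    """
    vals = fmap.values
    fig, ax = plt.subplots(figsize=(4.5, 4.5), dpi=dpi)
    masked = np.ma.masked_invalid(vals)
    vmin = 0.0 if fmap.normalization == "minmax" else None
    vmax = 1.0 if fmap.normalization == "minmax" else None
    im = ax.imshow(masked, cmap=cmap, vmin=vmin, vmax=vmax)
    for ch, (r, c) in fmap.montage.placement.items():
        ax.text(c, r, ch, ha="center", va="center", fontsize=5)
    title = fmap.quantity
    if fmap.class_label is not None:
        title += f" | class {fmap.class_label}"
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(out_path, metadata={"Software": None})
    plt.close(fig)
    return out_path
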