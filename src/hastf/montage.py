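"""Electrode-montage 9x9 grid mapping.

EEG channels are laid out on the scalp following the international 10-20
system; arranging them in a 9x9 matrix that preserves their relative
anterior-posterior / left-right positions lets convolutional layers see
scalp geometry.  This module ships two canonical layouts (``deap32``,
``seed62``) as plain-text placement tables and provides the forward and
inverse mapping between per-channel feature vectors and 9x9 grids.
Unoccupied cells carry ``fill_value`` (0 by default); no interpolation is
performed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "MontageGrid",
    "GridTensor",
    "MappingError",
    "load_montage",
    "montage_channels",
    "map_to_grid",
    "unmap_from_grid",
]


class MappingError(ValueError):
    """Channel set and montage placement disagree."""


@dataclass(frozen=True)
class MontageGrid:
    """Injective placement of channel names onto a height x width grid."""

    name: str
    placement: dict[str, tuple[int, int]]
    height: int = 9
    width: int = 9
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        cells = list(self.placement.values())
        if len(set(cells)) != len(cells):
            raise MappingError(f"montage {self.name!r}: two channels share a cell")
        for ch, (r, c) in self.placement.items():
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise MappingError(f"channel {ch!r} at ({r},{c}) is out of bounds")

    @property
    def n_channels(self) -> int:
        return len(self.placement)

    @property
    def channel_names(self) -> list[str]:
        return list(self.placement)

    def occupancy_mask(self) -> np.ndarray:
        """Boolean (height, width) mask of occupied cells."""
        mask = np.zeros((self.height, self.width), dtype=bool)
        for r, c in self.placement.values():
            mask[r, c] = True
        return mask


def _read_placement(fh) -> dict[str, tuple[int, int]]:
    placement: dict[str, tuple[int, int]] = {}
    for row in csv.reader(line for line in fh if not line.lstrip().startswith("#")):
        if not row or row[0].strip().lower() == "channel":
            continue
        ch, r, c = row[0].strip(), int(row[1]), int(row[2])
        placement[ch] = (r, c)
    return placement


def load_montage(name_or_path: str | Path) -> MontageGrid:
    """Load a shipped montage by name (``deap32``/``seed62``) or a custom
    ``channel,row,col`` table from a file path."""
    name = str(name_or_path)
    if name in ("deap32", "seed62"):
        ref = resources.files("hastf.data").joinpath(f"{name}.csv")
        with ref.open("r") as fh:
            return MontageGrid(name=name, placement=_read_placement(fh))
    path = Path(name_or_path)
    if not path.exists():
        raise MappingError(f"unknown montage {name!r} (not shipped, not a file)")
    with path.open() as fh:
        return MontageGrid(name=path.stem, placement=_read_placement(fh))


def montage_channels(n_channels: int) -> list[str]:
    """Channel order of the shipped montage with the given channel count."""
    if n_channels == 32:
        return load_montage("deap32").channel_names
    if n_channels == 62:
        return load_montage("seed62").channel_names
    raise MappingError(
        f"no shipped montage with {n_channels} channels; supply channel names"
    )


@dataclass
class GridTensor:
    """Per-patch band x 9 x 9 spatial DE maps.

    values has shape (windows n, patches T, bands B, height, width); cells
    not present in the montage placement always equal ``fill_value``.
    """

    values: np.ndarray
    montage: MontageGrid
    window_labels: np.ndarray
    band_names: list[str] = field(default_factory=list)
    subject_id: str = ""
    window_trials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 5:
            raise ValueError("values must be (n, T, B, h, w)")
        if self.values.shape[-2:] != (self.montage.height, self.montage.width):
            raise MappingError("grid shape does not match montage")


def map_to_grid(pt, mg: MontageGrid) -> GridTensor:
    """Scatter a PatchTensor's channel axis onto the montage grid.

    Every channel must have a placement; the inverse is
    :func:`unmap_from_grid`, exact on occupied cells.
    """
    missing = [ch for ch in pt.channel_names if ch not in mg.placement]
    if missing:
        raise MappingError(f"channels missing from montage {mg.name!r}: {missing}")
    n, T, B, C = pt.values.shape
    grid = np.full((n, T, B, mg.height, mg.width), mg.fill_value, dtype=np.float64)
    for ci, ch in enumerate(pt.channel_names):
        r, c = mg.placement[ch]
        grid[..., r, c] = pt.values[..., ci]
    return GridTensor(
        values=grid,
        montage=mg,
        window_labels=np.asarray(pt.window_labels),
        band_names=list(pt.band_names),
        subject_id=pt.subject_id,
        window_trials=None if pt.window_trials is None else np.asarray(pt.window_trials),
    )


def unmap_from_grid(gt: GridTensor, channel_names: list[str] | None = None):
    """Gather occupied grid cells back into a PatchTensor (exact inverse).

    Nonzero values in unoccupied cells indicate a corrupted grid: they are
    dropped with a warning reporting how many cells were affected.
    """
    from .preprocess import PatchTensor  # local import to avoid a cycle

    mg = gt.montage
    names = channel_names if channel_names is not None else mg.channel_names
    missing = [ch for ch in names if ch not in mg.placement]
    if missing:
        raise MappingError(f"channels missing from montage {mg.name!r}: {missing}")

    mask = mg.occupancy_mask()
    corrupted = int(np.count_nonzero(gt.values[..., ~mask] != mg.fill_value))
    if corrupted:
        warnings.warn(
            f"{corrupted} nonzero values in unoccupied cells were dropped",
            RuntimeWarning,
            stacklevel=2,
        )

    n, T, B = gt.values.shape[:3]
    out = np.empty((n, T, B, len(names)))
    for ci, ch in enumerate(names):
        r, c = mg.placement[ch]
        out[..., ci] = gt.values[..., r, c]
    return PatchTensor(
        values=out,
        band_names=list(gt.band_names),
        channel_names=list(names),
        window_labels=np.asarray(gt.window_labels),
        subject_id=gt.subject_id,
        window_trials=gt.window_trials,
    )
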