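"""HDF5 persistence for recordings and feature tensors, plus readers for
matrix-container exports of public emotion datasets.

Internal recording layout: datasets ``/data`` (trials x channels x
samples) and ``/labels``; attributes ``fs``, ``channel_names``,
``baseline_samples``, ``subject_id``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .preprocess import PatchTensor, threshold_ratings
from .synthetic import RawRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_patch_tensor",
    "load_patch_tensor",
    "load_deap_mat",
    "save_checkpoint",
    "load_checkpoint",
]


def save_recording(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("labels", data=np.asarray(rec.labels))
        f.attrs["fs"] = rec.fs
        f.attrs["channel_names"] = [str(c) for c in rec.channel_names]
        f.attrs["baseline_samples"] = rec.baseline_samples
        f.attrs["subject_id"] = rec.subject_id
    return path


def load_recording(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            subject_id=str(f.attrs["subject_id"]),
            data=f["data"][...],
            fs=float(f.attrs["fs"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            labels=f["labels"][...],
            baseline_samples=int(f.attrs["baseline_samples"]),
        )


def save_patch_tensor(pt: PatchTensor, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=pt.values)
        f.create_dataset("window_labels", data=np.asarray(pt.window_labels))
        if pt.window_trials is not None:
            f.create_dataset("window_trials", data=np.asarray(pt.window_trials))
        f.attrs["band_names"] = pt.band_names
        f.attrs["channel_names"] = pt.channel_names
        f.attrs["subject_id"] = pt.subject_id
    return path


def load_patch_tensor(path: str | Path) -> PatchTensor:
    with h5py.File(path, "r") as f:
        return PatchTensor(
            values=f["values"][...],
            band_names=[str(b) for b in f.attrs["band_names"]],
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            window_labels=f["window_labels"][...],
            subject_id=str(f.attrs["subject_id"]),
            window_trials=f["window_trials"][...] if "window_trials" in f else None,
        )


def save_checkpoint(net, path: str | Path, manifest: dict | None = None) -> Path:
    """Write network weights to a single-file archive with a JSON manifest
    (variant, parameter count, plus any caller-supplied metadata)."""
    import json

    path = Path(path)
    meta = {
        "variant": getattr(net, "variant", None),
        "n_parameters": net.n_parameters(),
        **(manifest or {}),
    }
    np.savez(path, __manifest__=json.dumps(meta), **net.state_dict())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(net, path: str | Path) -> dict:
    """Restore weights saved by :func:`save_checkpoint`; returns the manifest."""
    import json

    with np.load(path, allow_pickle=False) as f:
        manifest = json.loads(str(f["__manifest__"]))
        state = {k: f[k] for k in f.files if k != "__manifest__"}
    net.load_state_dict(state)
    return manifest


def load_deap_mat(
    path: str | Path,
    label_dim: int = 1,
    threshold: float = 5.0,
    channel_names: list[str] | None = None,
    fs: float = 128.0,
    baseline_s: float = 3.0,
) -> RawRecording:
    """Read a per-subject matrix export in the 40-trial layout.

    Expects variables ``data`` (40 x 40 x 8064; the first 32 rows of the
    channel axis are EEG) and ``labels`` (40 x 4 continuous ratings:
    valence, arousal, dominance, liking — ``label_dim`` selects which,
    0-based).  Ratings are binarized at ``threshold`` (high iff rating >
    threshold).
    """
    from scipy.io import loadmat

    from .montage import montage_channels

    mat = loadmat(str(path))
    data = np.asarray(mat["data"], dtype=np.float64)[:, :32, :]
    ratings = np.asarray(mat["labels"], dtype=float)[:, label_dim]
    labels = threshold_ratings(ratings, threshold)
    names = channel_names or montage_channels(32)
    return RawRecording(
        subject_id=Path(path).stem,
        data=data,
        fs=fs,
        channel_names=list(names),
        labels=labels,
        baseline_samples=int(round(baseline_s * fs)),
    )
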