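"""Array-container (HDF5) and table I/O for recordings, models and results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .hmm import HmmModel
from .preprocess import ParcelRecording

__all__ = [
    "write_recordings",
    "read_recordings",
    "write_model",
    "read_model",
    "write_ground_truth",
    "read_ground_truth",
]


def write_recordings(path: str | Path, recordings: list[ParcelRecording], seed: int | None = None) -> None:
    """One dataset per subject, sampling rate and seed as attributes."""
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        for rec in recordings:
            d = f.create_dataset(rec.subject_id, data=rec.data)
            d.attrs["sampling_rate"] = rec.sampling_rate
            if rec.bad_mask is not None:
                f.create_dataset(f"{rec.subject_id}__bad_mask", data=rec.bad_mask)


def read_recordings(path: str | Path) -> list[ParcelRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            if name.endswith("__bad_mask"):
                continue
            d = f[name]
            mask = f[f"{name}__bad_mask"][...] if f"{name}__bad_mask" in f else None
            out.append(ParcelRecording(name, d[...], float(d.attrs["sampling_rate"]), mask))
    return out


def write_model(path: str | Path, model: HmmModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("covariances", data=model.covariances)
        f.create_dataset("transition", data=model.transition)
        f.create_dataset("initial", data=model.initial)
        f.attrs["fit_score"] = model.fit_score
        if model.loglik_history is not None:
            f.create_dataset("loglik_history", data=model.loglik_history)


def read_model(path: str | Path) -> HmmModel:
    with h5py.File(path, "r") as f:
        hist = f["loglik_history"][...] if "loglik_history" in f else None
        return HmmModel(
            f["covariances"][...],
            f["transition"][...],
            f["initial"][...],
            float(f.attrs["fit_score"]),
            hist,
        )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_ground_truth(path: str | Path, truth: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(truth), indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
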