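"""File formats and persistence: WAV, annotation CSV, Gammatone-spectrogram
containers, model bundles and configuration hashing.

Conventions: times are seconds with 6 decimal places, intervals half-open
[start_s, end_s), labels lowercase class abbreviations (plus ``FP``/``uc``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, is_dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from usvpipe.errors import EmptyInputError
from usvpipe.model import ClassifierConfig, SnapshotSet
from usvpipe.ensemble import BaggedEnsemble


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sample_rate: int,
              dtype: str = "float32") -> None:
    """Write a mono WAV (float32 by default, or 16-bit PCM)."""
    x = np.asarray(waveform, dtype=np.float64)
    if dtype == "float32":
        wavfile.write(path, sample_rate, x.astype(np.float32))
    elif dtype == "pcm16":
        scaled = np.clip(x, -1.0, 1.0) * 32767
        wavfile.write(path, sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'pcm16'")


def read_wav(path, target_rate: int | None = None) -> tuple[np.ndarray, int]:
    """Read a WAV as float samples in [-1, 1], optionally resampling.

    Multichannel files collapse to channel 0 with a warning.
    """
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise EmptyInputError(f"{path}: empty WAV file")
    if data.ndim > 1:
        warnings.warn(f"{path}: multichannel WAV, using channel 0")
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / info.max  # matches the writer's scale
    else:
        data = data.astype(np.float64)
    if target_rate is not None and target_rate != rate:
        frac = Fraction(int(target_rate), int(rate)).limit_denominator(10000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator)
        rate = target_rate
    return data, rate


# ---------------------------------------------------------------------------
# annotation / detection / prediction tables
# ---------------------------------------------------------------------------

def write_annotations(path, rows, extra_columns: dict | None = None) -> None:
    """Write (start_s, end_s, label) rows; intervals are half-open."""
    df = pd.DataFrame(rows, columns=["start_s", "end_s", "label"])
    if extra_columns:
        for k, v in extra_columns.items():
            df[k] = v
    df["start_s"] = df["start_s"].map(lambda v: f"{v:.6f}")
    df["end_s"] = df["end_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read an annotation table, tolerating reordered columns by name."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for want, aliases in (("start_s", ("start_s", "start", "start time")),
                          ("end_s", ("end_s", "end", "end time")),
                          ("label", ("label", "class", "type"))):
        for alias in aliases:
            if alias in cols:
                rename[cols[alias]] = want
                break
    df = df.rename(columns=rename)
    if "start_s" not in df.columns:
        raise ValueError(f"{path}: no start-time column found")
    df["start_s"] = df["start_s"].astype(float)
    if "end_s" in df.columns:
        df["end_s"] = df["end_s"].astype(float)
    return df.sort_values("start_s").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GS containers
# ---------------------------------------------------------------------------

def save_gs_container(path, gs_list, labels=None) -> None:
    """Persist Gammatone spectrograms as an .npz plus a JSON sidecar."""
    path = Path(path)
    values = np.stack([g.values for g in gs_list]).astype(np.float32)
    np.savez_compressed(path, values=values)
    meta = {
        "n": len(gs_list),
        "element_ids": [g.element_id for g in gs_list],
        "labels": list(labels) if labels is not None else [g.label for g in gs_list],
        "frame_hop": gs_list[0].frame_hop if gs_list else None,
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_gs_container(path) -> tuple[np.ndarray, list]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        values = data["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return values, meta["labels"]


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def config_hash(config) -> str:
    """Stable short hash of a configuration mapping or dataclass."""
    if is_dataclass(config):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_bag(directory, bag: BaggedEnsemble) -> None:
    """Persist a bagged ensemble as one .npz per member plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(bag.members):
        arrays = {}
        for ci, checkpoint in enumerate(member.checkpoints):
            for ai, arr in enumerate(checkpoint):
                arrays[f"c{ci}_a{ai}"] = arr
        np.savez_compressed(directory / f"member_{i}.npz", **arrays)
    cfg = asdict(bag.members[0].config)
    manifest = {
        "b": bag.b,
        "mode": bag.mode,
        "class_names": bag.class_names,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "n_checkpoints": len(bag.members[0].checkpoints),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bag(directory) -> BaggedEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    for key in ("filters_per_layer", "first_kernel", "later_kernel",
                "first_stride", "input_shape"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    config = ClassifierConfig(**cfg_dict)
    members = []
    for i in range(manifest["b"]):
        with np.load(directory / f"member_{i}.npz") as data:
            checkpoints = []
            for ci in range(manifest["n_checkpoints"]):
                ai = 0
                arrays = []
                while f"c{ci}_a{ai}" in data:
                    arrays.append(data[f"c{ci}_a{ai}"])
                    ai += 1
                checkpoints.append(arrays)
        members.append(SnapshotSet(config=config,
                                   class_names=manifest["class_names"],
                                   checkpoints=checkpoints, history=[]))
    return BaggedEnsemble(members=members, mode=manifest["mode"],
                          class_names=manifest["class_names"])
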