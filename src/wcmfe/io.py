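"""CSV readers/writers and dataset manifests.

Two trial dialects are supported, both comma-separated, UTF-8, '.' decimal,
header required:

* **wide** — one file per trial; first column ``channel`` holds the electrode
  label, the remaining columns ``s1..sN`` the samples. Sampling rate and
  class label live in the dataset manifest (or are passed explicitly).
* **long** — one table for many trials with columns
  ``trial, channel, sample_index, value, label``.

A dataset directory is a manifest.json (sampling rate, per-file labels, seed,
config hash) plus one wide CSV per trial.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trials import EEGTrial

__all__ = [
    "config_hash",
    "write_trial_csv",
    "read_trial_csv",
    "write_long_csv",
    "read_long_csv",
    "save_dataset",
    "load_dataset",
    "write_features_csv",
    "read_features_csv",
    "read_accuracies_csv",
    "write_accuracies_csv",
]


def config_hash(cfg: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def write_trial_csv(trial: EEGTrial, path) -> None:
    """Write one trial in the wide dialect (row per channel)."""
    df = pd.DataFrame(trial.data,
                      columns=[f"s{i + 1}" for i in range(trial.n_samples)])
    df.insert(0, "channel", list(trial.channel_names))
    df.to_csv(path, index=False, float_format="%.10g")


def read_trial_csv(path, fs: float, label: str | None = None) -> EEGTrial:
    """Read one wide-dialect trial file."""
    df = pd.read_csv(path)
    if "channel" not in df.columns:
        raise ValueError(f"{path}: missing required 'channel' column")
    names = tuple(str(c) for c in df["channel"])
    data = df.drop(columns="channel").to_numpy(dtype=float)
    return EEGTrial(data=data, fs=fs, channel_names=names, label=label)


def write_long_csv(trials, labels, path) -> None:
    """Write many trials as one long-format table."""
    rows = []
    for t_idx, (trial, lab) in enumerate(zip(trials, labels)):
        for c, name in enumerate(trial.channel_names):
            rows.append(pd.DataFrame({
                "trial": t_idx,
                "channel": name,
                "sample_index": np.arange(1, trial.n_samples + 1),
                "value": trial.data[c],
                "label": lab,
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.10g")


def read_long_csv(path, fs: float):
    """Read a long-format table back into ``(trials, labels)``."""
    df = pd.read_csv(path)
    required = {"trial", "channel", "sample_index", "value", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trials, labels = [], []
    for t_idx, grp in df.groupby("trial", sort=True):
        chans = sorted(grp["channel"].unique())
        mat = []
        for ch in chans:
            sub = grp[grp["channel"] == ch].sort_values("sample_index")
            mat.append(sub["value"].to_numpy(dtype=float))
        lab = str(grp["label"].iloc[0])
        trials.append(EEGTrial(data=np.vstack(mat), fs=fs,
                               channel_names=tuple(chans), label=lab))
        labels.append(lab)
    return trials, np.asarray(labels, dtype=str)


def save_dataset(trials, labels, out_dir, cfg: dict, seed: int) -> Path:
    """Write a dataset directory (wide CSVs + manifest); returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, trial in enumerate(trials):
        name = f"trial_{i:04d}.csv"
        write_trial_csv(trial, out / name)
        files.append(name)
    fs = float(trials[0].fs) if trials else None
    manifest = {
        "fs": fs,
        "n_trials": len(trials),
        "files": files,
        "labels": [str(l) for l in labels],
        "seed": int(seed),
        "config": cfg,
        "config_hash": config_hash(cfg),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_dataset(data_dir):
    """Read a dataset directory; returns ``(trials, labels, manifest)``."""
    data_dir = Path(data_dir)
    mpath = data_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {data_dir}")
    manifest = json.loads(mpath.read_text())
    trials, labels = [], []
    for fname, lab in zip(manifest["files"], manifest["labels"]):
        trials.append(read_trial_csv(data_dir / fname, fs=manifest["fs"], label=lab))
        labels.append(lab)
    return trials, np.asarray(labels, dtype=str), manifest


def write_features_csv(path, trial_ids, labels, features, feature_names) -> None:
    """Feature table: trial_id, label, then one column per feature."""
    F = np.asarray(features, dtype=float)
    df = pd.DataFrame(F, columns=list(feature_names))
    df.insert(0, "label", list(labels))
    df.insert(0, "trial_id", list(trial_ids))
    df.to_csv(path, index=False, float_format="%.12g")


def read_features_csv(path):
    """Read a feature table; returns ``(trial_ids, labels, F, names)``."""
    df = pd.read_csv(path)
    for col in ("trial_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    names = [c for c in df.columns if c not in ("trial_id", "label")]
    F = df[names].to_numpy(dtype=float)
    return df["trial_id"].to_numpy(), df["label"].to_numpy(dtype=str), F, names


def write_accuracies_csv(path, accuracies) -> None:
    pd.DataFrame({"accuracy": np.asarray(accuracies, dtype=float)}).to_csv(
        path, index=False, float_format="%.12g")


def read_accuracies_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "accuracy" not in df.columns:
        raise ValueError(f"{path}: missing required column 'accuracy'")
    return df["accuracy"].to_numpy(dtype=float)
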