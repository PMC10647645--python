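"""On-disk formats: delimited epoch matrices with JSON sidecars, FC
archives, manifests.

An epoch is stored as a tab-separated ROI x sample matrix whose first
column holds the ROI labels, next to a ``<stem>.json`` sidecar with
participant/group/condition/sampling-rate metadata.  A cohort directory
holds one epoch file per recording plus ``manifest.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import FcWindowSeries, WindowPlan
from .synth import RoiEpoch

SIDECAR_FIELDS = ("participant_id", "group", "condition", "sampling_rate_hz")


class SchemaError(ValueError):
    """A file failed schema validation on read."""


def epoch_stem(epoch: RoiEpoch) -> str:
    return f"{epoch.participant_id}_{epoch.condition}_e{epoch.epoch_index:03d}"


def write_epoch(epoch: RoiEpoch, directory) -> Path:
    """Write one epoch (TSV matrix + JSON sidecar); returns the TSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = epoch_stem(epoch)
    tsv = directory / f"{stem}.tsv"
    frame = pd.DataFrame(
        epoch.data,
        index=pd.Index(epoch.roi_labels, name="roi"),
        columns=[f"s{i}" for i in range(epoch.n_samples)],
    )
    frame.to_csv(tsv, sep="\t", float_format="%.6g")
    sidecar = {
        "participant_id": epoch.participant_id,
        "group": epoch.group,
        "condition": epoch.condition,
        "sampling_rate_hz": epoch.sampling_rate_hz,
        "epoch_index": epoch.epoch_index,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_epoch(tsv_path) -> RoiEpoch:
    """Read one epoch, validating the sidecar schema."""
    tsv_path = Path(tsv_path)
    sidecar_path = tsv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"{tsv_path}: missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    missing = [f for f in SIDECAR_FIELDS if f not in meta]
    if missing:
        raise SchemaError(f"{sidecar_path}: sidecar missing field(s) {missing}")
    frame = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if frame.index.name != "roi":
        raise SchemaError(f"{tsv_path}: first column must be named 'roi'")
    return RoiEpoch(
        participant_id=str(meta["participant_id"]),
        group=str(meta["group"]),
        condition=str(meta["condition"]),
        roi_labels=tuple(str(r) for r in frame.index),
        data=frame.to_numpy(dtype=float),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        epoch_index=int(meta.get("epoch_index", 0)),
    )


def write_cohort(epochs: list[RoiEpoch], manifest: pd.DataFrame, directory) -> Path:
    """Write every epoch plus ``manifest.csv``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for epoch in epochs:
        paths.append(str(write_epoch(epoch, directory).name))
    if len(paths) != len(manifest):
        raise ValueError("manifest row count does not match epoch count")
    manifest["path"] = paths
    out = directory / "manifest.csv"
    manifest.to_csv(out, index=False)
    return out


def read_cohort(directory) -> tuple[list[RoiEpoch], pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise SchemaError(f"{directory}: missing manifest.csv")
    manifest = pd.read_csv(manifest_path)
    if "path" not in manifest.columns:
        raise SchemaError(f"{manifest_path}: missing 'path' column")
    epochs = [read_epoch(directory / p) for p in manifest["path"]]
    return epochs, manifest


def write_fc_series(fcs: FcWindowSeries, directory) -> Path:
    """Write one FC series as a compressed array archive plus JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{fcs.participant_id}_{fcs.condition}_e{fcs.epoch_index:03d}_fc"
    npz = directory / f"{stem}.npz"
    np.savez_compressed(npz, windows=fcs.windows)
    meta = {
        "participant_id": fcs.participant_id,
        "group": fcs.group,
        "condition": fcs.condition,
        "epoch_index": fcs.epoch_index,
        "roi_labels": list(fcs.roi_labels),
        "nan_pair_count": fcs.nan_pair_count,
        "plan": {
            "window_samples": fcs.plan.window_samples,
            "step_samples": fcs.plan.step_samples,
            "n_windows": fcs.plan.n_windows,
            "window_ms": fcs.plan.window_ms,
            "overlap_fraction": fcs.plan.overlap_fraction,
        },
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return npz


def read_fc_series(npz_path) -> FcWindowSeries:
    npz_path = Path(npz_path)
    meta_path = npz_path.with_suffix(".json")
    if not meta_path.exists():
        raise SchemaError(f"{npz_path}: missing sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    windows = np.load(npz_path)["windows"]
    plan = WindowPlan(**meta["plan"])
    return FcWindowSeries(
        participant_id=meta["participant_id"],
        group=meta["group"],
        condition=meta["condition"],
        epoch_index=meta["epoch_index"],
        roi_labels=tuple(meta["roi_labels"]),
        windows=windows,
        plan=plan,
        nan_pair_count=meta.get("nan_pair_count", 0),
    )
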