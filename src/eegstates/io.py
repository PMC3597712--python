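"""Delimited-text interchange for epochs, manifests and ground truth.

Native format: one tab-separated matrix file per epoch with a header row of
channel names (rows are samples, columns are channels; the orientation and
metadata are recorded in '#'-prefixed header lines), plus a cohort manifest
listing subject, group, condition, age and the epoch file path.  EDF input is
accepted through an adapter built on MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import EpochRecord
from .synthetic import CohortTruth

__all__ = [
    "write_epoch",
    "read_epoch",
    "write_cohort",
    "read_manifest",
    "read_epochs",
    "read_edf_epochs",
]


def write_epoch(path: str | Path, epoch: EpochRecord, header_extra: dict | None = None) -> None:
    """Write one epoch as TSV: '#' metadata lines, channel-name header, samples as rows."""
    path = Path(path)
    meta = {
        "fs": epoch.fs,
        "subject": epoch.subject_id,
        "group": epoch.group,
        "condition": epoch.condition,
        "epoch_index": epoch.epoch_index,
        "age": epoch.age,
        "orientation": "rows=samples, columns=channels; 0-based half-open windows downstream",
    }
    if header_extra:
        meta.update(header_extra)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(epoch.channel_names) + "\n")
        np.savetxt(fh, epoch.data.T, fmt="%.10g", delimiter="\t")


def read_epoch(path: str | Path) -> EpochRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        channel_names = line.rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    age = meta.get("age")
    return EpochRecord(
        data=data.T,
        fs=float(meta["fs"]),
        subject_id=meta.get("subject", ""),
        group=meta.get("group", ""),
        condition=meta.get("condition", ""),
        epoch_index=int(meta.get("epoch_index", 0)),
        channel_names=channel_names,
        age=None if age in (None, "", "None") else float(age),
    )


def write_cohort(
    directory: str | Path,
    epochs: list[EpochRecord],
    truth: CohortTruth | None = None,
    header_extra: dict | None = None,
) -> Path:
    """Write every epoch plus a manifest (and a ground-truth sidecar if given).

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ep in epochs:
        fname = f"{ep.subject_id}_{ep.group}_{ep.condition}_ep{ep.epoch_index}.tsv"
        write_epoch(directory / fname, ep, header_extra=header_extra)
        rows.append(
            {
                "subject": ep.subject_id,
                "group": ep.group,
                "condition": ep.condition,
                "epoch_index": ep.epoch_index,
                "age": ep.age,
                "fs": ep.fs,
                "path": fname,
            }
        )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if truth is not None:
        truth.summary.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
        sidecar = {
            "note": "synthetic cohort; per-epoch/channel true regime counts and dwell times",
            "columns": list(truth.summary.columns),
        }
        (directory / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def read_manifest(manifest: str | Path) -> pd.DataFrame:
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    if df.empty:
        raise ValueError(f"empty manifest: {manifest}")
    return df


def read_epochs(manifest: str | Path) -> list[EpochRecord]:
    """Load every epoch referenced by a manifest, enforcing channel consistency."""
    manifest = Path(manifest)
    df = read_manifest(manifest)
    epochs = []
    chans_by_subject: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        path = manifest.parent / row["path"]
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing epoch file: {path}")
        ep = read_epoch(path)
        prev = chans_by_subject.setdefault(ep.subject_id, ep.channel_names)
        if prev != ep.channel_names:
            raise ValueError(f"channel mismatch across epochs of subject {ep.subject_id}")
        epochs.append(ep)
    return epochs


def read_edf_epochs(
    path: str | Path,
    epoch_length_s: float,
    subject_id: str = "",
    group: str = "",
    condition: str = "",
) -> list[EpochRecord]:
    """Cut an EDF recording into consecutive fixed-length epochs.

    Uses MNE's EDF reader; channel names and the sampling rate are preserved.
    The per-channel mean is removed from each epoch.
    """
    import mne  # deferred: EDF support is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    n_ep = int(data.shape[1] // round(epoch_length_s * fs))
    if n_ep == 0:
        raise ValueError("recording shorter than one epoch")
    step = int(round(epoch_length_s * fs))
    epochs = []
    for i in range(n_ep):
        chunk = data[:, i * step : (i + 1) * step]
        chunk = chunk - chunk.mean(axis=1, keepdims=True)
        epochs.append(
            EpochRecord(
                data=chunk,
                fs=fs,
                subject_id=subject_id or Path(path).stem,
                group=group,
                condition=condition,
                epoch_index=i,
                channel_names=list(raw.ch_names),
            )
        )
    return epochs
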