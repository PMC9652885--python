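"""On-disk formats: epoch-set container (NPZ tensor + JSON sidecar), cohort
label tables, ranking/report CSVs, and a minimal EDF reader/writer for
continuous recordings."""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

# ---------------------------------------------------------------------------
# epoch-set container

def save_epoch_set(es: EpochSet, directory: "str | Path") -> Path:
    """Write <subject_id>.npz plus <subject_id>.json sidecar; returns the
    npz path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npz = directory / f"{es.subject_id}.npz"
    np.savez_compressed(npz, data=es.data)
    sidecar = {
        "subject_id": es.subject_id,
        "group": es.group,
        "fs": es.fs,
        "channel_labels": list(es.channel_labels),
        "epoch_seconds": es.n_samples / es.fs,
    }
    (directory / f"{es.subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    return npz


def load_epoch_set(npz_path: "str | Path") -> EpochSet:
    npz_path = Path(npz_path)
    meta = json.loads(npz_path.with_suffix(".json").read_text())
    with np.load(npz_path) as f:
        data = f["data"]
    return EpochSet(subject_id=meta["subject_id"], group=meta["group"],
                    data=data, fs=meta["fs"],
                    channel_labels=tuple(meta["channel_labels"]))


def save_cohort(epoch_sets: Sequence[EpochSet], directory: "str | Path") -> Path:
    """Write every subject plus a labels.csv index; returns the labels path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for es in epoch_sets:
        save_epoch_set(es, directory)
        rows.append({"subject_id": es.subject_id, "label": es.group})
    labels_path = directory / "labels.csv"
    pd.DataFrame(rows).to_csv(labels_path, index=False)
    return labels_path


def load_cohort(directory: "str | Path") -> List[EpochSet]:
    directory = Path(directory)
    labels = pd.read_csv(directory / "labels.csv")
    return [load_epoch_set(directory / f"{sid}.npz")
            for sid in labels["subject_id"]]


# ---------------------------------------------------------------------------
# minimal EDF (16-bit European Data Format) support

_EDF_HEADER = 256
_EDF_PER_SIGNAL = 256


def read_edf(path: "str | Path") -> Tuple[np.ndarray, float, List[str]]:
    """Read a (non-annotated) EDF file.

    Returns (channels x samples array in physical units, sampling rate Hz,
    channel labels). All signals must share one sampling rate.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _EDF_HEADER:
        raise ValueError("file too short to be EDF")
    def txt(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()
    n_records = int(txt(236, 244))
    record_seconds = float(txt(244, 252))
    ns = int(txt(252, 256))
    off = _EDF_HEADER
    fields = {}
    widths = [("label", 16), ("transducer", 80), ("dimension", 8),
              ("phys_min", 8), ("phys_max", 8), ("dig_min", 8),
              ("dig_max", 8), ("prefilter", 80), ("n_samples", 8),
              ("reserved", 32)]
    for name, width in widths:
        fields[name] = [txt(off + i * width, off + (i + 1) * width)
                        for i in range(ns)]
        off += ns * width
    labels = fields["label"]
    n_samp = [int(v) for v in fields["n_samples"]]
    if len(set(n_samp)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr = n_samp[0]
    fs = spr / record_seconds
    phys_min = np.array([float(v) for v in fields["phys_min"]])
    phys_max = np.array([float(v) for v in fields["phys_max"]])
    dig_min = np.array([float(v) for v in fields["dig_min"]])
    dig_max = np.array([float(v) for v in fields["dig_max"]])

    payload = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_records * ns * spr
    if payload.size < expected:
        raise ValueError("EDF payload shorter than the header declares")
    payload = payload[:expected].reshape(n_records, ns, spr)
    digital = payload.transpose(1, 0, 2).reshape(ns, n_records * spr).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    physical = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return physical, fs, labels


def write_edf(
    path: "str | Path",
    data: np.ndarray,
    fs: float,
    labels: Sequence[str],
    record_seconds: float = 1.0,
) -> None:
    """Write a channels x samples array as a 16-bit EDF file (test/demo
    helper; truncates to whole data records)."""
    data = np.asarray(data, dtype=float)
    ns, total = data.shape
    if len(labels) != ns:
        raise ValueError("labels must match channel count")
    spr = int(round(fs * record_seconds))
    n_records = total // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    data = data[:, : n_records * spr]
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767
    digital = ((data - phys_min[:, None]) / span[:, None]
               * (dig_max - dig_min) + dig_min)
    digital = np.round(digital).astype("<i2")

    def pad(value: str, width: int) -> bytes:
        b = value.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("eegsel", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(_EDF_HEADER + ns * _EDF_PER_SIGNAL), 8), pad("", 44),
        pad(str(n_records), 8), pad(f"{record_seconds:g}", 8), pad(str(ns), 4),
    ])
    cols = [
        [pad(lab, 16) for lab in labels],
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [pad(str(dig_min), 8)] * ns,
        [pad(str(dig_max), 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(spr), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    signal_header = b"".join(b"".join(col) for col in cols)
    body = digital.reshape(ns, n_records, spr).transpose(1, 0, 2).tobytes()
    Path(path).write_bytes(header + signal_header + body)
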