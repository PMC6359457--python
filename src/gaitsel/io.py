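"""CSV/JSON glue for recordings, feature tables, and Pareto archives.

Recording CSV: header ``time,<ch1>,<ch2>,...,label`` with time in seconds.
Feature-table CSV: one column per expanded layout entry, named
``TYPE@channel``, ``TYPE@chanA-chanB`` for pairs, ``AR4.k@channel`` for
k = 1..4, plus a final ``label`` column.
Archive JSON: ``{"points": [{"objectives": [...], "payload": ...}, ...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureLayout, FeatureTable, LayoutEntry
from .pareto import ParetoArchive, ParetoPoint
from .windowing import RawRecording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_feature_table_csv",
    "read_feature_table_csv",
    "write_archive_json",
    "read_archive_json",
]

_FLOAT_DECIMALS = 10  # fixed serialization precision => byte-stable artifacts


def write_recording_csv(recording: RawRecording, path: str | Path) -> None:
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"time": t})
    for i, name in enumerate(recording.channel_names):
        df[name] = recording.samples[:, i]
    df["label"] = recording.labels
    df.to_csv(path, index=False, float_format=f"%.{_FLOAT_DECIMALS}g")


def read_recording_csv(path: str | Path, fs: float | None = None) -> RawRecording:
    """Load a recording; uniform sampling is inferred from the time column
    and validated against ``fs`` when declared."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[0] != "time" or cols[-1] != "label":
        raise ValueError("recording CSV must be time,<channels...>,label")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording must have at least 2 samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise ValueError("recording is not uniformly sampled")
    inferred_fs = 1.0 / dt[0]
    if fs is not None and abs(inferred_fs - fs) > 1e-3 * fs:
        raise ValueError(
            f"declared fs={fs} Hz but time column implies {inferred_fs:.6g} Hz"
        )
    channels = cols[1:-1]
    return RawRecording(
        samples=df[channels].to_numpy(dtype=float),
        fs=fs if fs is not None else inferred_fs,
        labels=df["label"].to_numpy(),
        channel_names=tuple(channels),
    )


def write_feature_table_csv(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.column_names())
    df["label"] = table.labels
    df.to_csv(path, index=False, float_format=f"%.{_FLOAT_DECIMALS}g")


def _parse_column_name(
    name: str, channel_index: dict[str, int]
) -> tuple[str, object, int]:
    """Returns (feature_type, target, ar_lag); ar_lag is 0 for scalars."""
    ftype, _, chan = name.partition("@")
    lag = 0
    if ftype.startswith("AR4."):
        lag = int(ftype.split(".")[1])
        ftype = "AR4"

    def chan_id(c: str) -> int:
        if c not in channel_index:
            channel_index[c] = len(channel_index)
        return channel_index[c]

    if ftype in ("COR", "ANG"):
        a, _, b = chan.partition("-")
        return ftype, (chan_id(a), chan_id(b)), lag
    return ftype, chan_id(chan), lag


def read_feature_table_csv(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature-table CSV must end with a 'label' column")
    labels = df["label"].to_numpy()
    feature_cols = [c for c in df.columns if c != "label"]
    channel_index: dict[str, int] = {}
    entries: list[LayoutEntry] = []
    layout_ok = True
    for name in feature_cols:
        if "@" not in name:
            layout_ok = False
            break
        ftype, target, lag = _parse_column_name(name, channel_index)
        if ftype == "AR4" and lag != 1:
            continue  # AR4.2..4 fold into the AR4.1 entry
        try:
            entries.append(LayoutEntry(ftype, target))
        except ValueError:
            layout_ok = False
            break
    layout = FeatureLayout(entries) if layout_ok else None
    if layout is not None and layout.n_columns != len(feature_cols):
        layout = None
    names = sorted(channel_index, key=channel_index.get) if layout_ok else None
    return FeatureTable(
        values=df[feature_cols].to_numpy(dtype=float),
        labels=labels,
        layout=layout,
        channel_names=tuple(names) if names else None,
    )


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, _FLOAT_DECIMALS)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), _FLOAT_DECIMALS)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_archive_json(archive: ParetoArchive, path: str | Path) -> None:
    payload = {
        "points": [
            {
                "objectives": _round_floats(list(p.objectives)),
                "payload": _round_floats(p.payload),
            }
            for p in archive.points
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_archive_json(path: str | Path) -> ParetoArchive:
    data = json.loads(Path(path).read_text())
    return ParetoArchive(
        [
            ParetoPoint(
                objectives=tuple(p["objectives"]), payload=p.get("payload")
            )
            for p in data["points"]
        ]
    )
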