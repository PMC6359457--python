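"""Framing of labeled multichannel recordings.

A recording is cut into fixed-length frames either disjointly or with a
sliding window (increment ``I`` ms).  Disjoint windowing is the special case
``I == Lf``.  Valid configurations respect the declared processing budget:
``tau <= Lf`` (disjoint) and ``tau <= I <= Lf`` (overlapped).  The budget is
carried and checked as configuration, never measured.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RawRecording",
    "WindowingConfig",
    "Frame",
    "segment_frames",
    "assign_frame_label",
]


@dataclass
class RawRecording:
    """Multichannel labeled time series: (time x channels) at a fixed rate."""

    samples: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channels) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != sample count "
                f"{self.samples.shape[0]}"
            )
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.samples.shape[1])
            )
        elif len(self.channel_names) != self.samples.shape[1]:
            raise ValueError("channel_names length must match channel count")
        else:
            self.channel_names = tuple(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs


@dataclass(frozen=True)
class WindowingConfig:
    """Frame length/increment in milliseconds plus the processing budget."""

    frame_ms: float
    increment_ms: float | None = None
    mode: str = "disjoint"
    processing_budget_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("disjoint", "overlapped"):
            raise ValueError(f"unknown windowing mode {self.mode!r}")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if self.mode == "disjoint":
            if self.increment_ms is not None and self.increment_ms != self.frame_ms:
                raise ValueError("disjoint windowing requires increment == frame")
            object.__setattr__(self, "increment_ms", self.frame_ms)
            if self.processing_budget_ms > self.frame_ms:
                raise ValueError(
                    "processing budget exceeds frame length (disjoint mode)"
                )
        else:
            if self.increment_ms is None:
                raise ValueError("overlapped windowing requires increment_ms")
            if self.increment_ms > self.frame_ms:
                raise ValueError("overlapped windowing requires I <= Lf")
            if self.processing_budget_ms > self.increment_ms:
                raise ValueError("processing budget exceeds increment (overlapped)")
        if self.increment_ms is not None and self.increment_ms <= 0:
            raise ValueError("increment_ms must be positive")

    def frame_samples(self, fs: float) -> int:
        n = self.frame_ms * fs / 1000.0
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"frame_ms={self.frame_ms} at fs={fs} Hz is not an integer "
                "number of samples"
            )
        return int(round(n))

    def increment_samples(self, fs: float) -> int:
        assert self.increment_ms is not None
        n = self.increment_ms * fs / 1000.0
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"increment_ms={self.increment_ms} at fs={fs} Hz is not an "
                "integer number of samples"
            )
        return int(round(n))


@dataclass
class Frame:
    """One fixed-length window of samples with a single assigned label."""

    data: np.ndarray
    start_index: int
    label: object

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def assign_frame_label(frame_sample_labels: Sequence) -> object:
    """Majority label of the samples; ties go to the latest tied label.

    Frames spanning a mode transition get one label; the latest sample best
    reflects current intent, hence the tie-break.
    """
    labels = list(frame_sample_labels)
    if not labels:
        raise ValueError("cannot label an empty frame")
    counts = Counter(labels)
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    if len(tied) == 1:
        return tied.pop()
    for lab in reversed(labels):
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def segment_frames(
    recording: RawRecording, config: WindowingConfig
) -> list[Frame]:
    """Cut a recording into frames; partial trailing frames are dropped.

    Frame ``k`` starts at sample ``k * I * fs / 1000``; the number of frames
    is ``floor((T - Lf) / I) + 1`` for a recording of duration ``T`` ms (zero
    when the recording is shorter than one frame).
    """
    flen = config.frame_samples(recording.fs)
    step = config.increment_samples(recording.fs)
    frames: list[Frame] = []
    for start in range(0, recording.n_samples - flen + 1, step):
        window = recording.samples[start : start + flen]
        label = assign_frame_label(recording.labels[start : start + flen])
        frames.append(Frame(data=window, start_index=start, label=label))
    return frames
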