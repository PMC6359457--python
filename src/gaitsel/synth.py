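"""Synthetic inputs: quasi-periodic 3-channel gait-like recordings and
planted labeled feature tables.

The simulator targets statistical structure only — mode-dependent cadence
and amplitude on three channels (vertical hip position, thigh angle, thigh
moment) — so every downstream stage can be exercised without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureTable
from .windowing import RawRecording

__all__ = [
    "ModeParams",
    "GaitSimConfig",
    "PlantedTableConfig",
    "simulate_gait_recording",
    "generate_planted_table",
    "default_schedule",
]

CHANNEL_NAMES = ("hip_position", "thigh_angle", "thigh_moment")


@dataclass(frozen=True)
class ModeParams:
    """Cadence (Hz) and per-channel oscillation amplitude for one gait mode."""

    cadence_hz: float
    amplitudes: tuple[float, float, float]


DEFAULT_MODE_PARAMS: dict[str, ModeParams] = {
    "ST": ModeParams(0.0, (0.0, 0.0, 0.0)),
    "SW": ModeParams(0.7, (0.02, 0.25, 0.4)),
    "NW": ModeParams(1.0, (0.03, 0.35, 0.6)),
    "FW": ModeParams(1.4, (0.04, 0.45, 0.8)),
}


def default_schedule() -> list[tuple[str, float]]:
    """~60 s sequence cycling standing and the three walking modes."""
    return [
        ("ST", 6.0),
        ("SW", 12.0),
        ("NW", 12.0),
        ("FW", 12.0),
        ("NW", 6.0),
        ("SW", 6.0),
        ("ST", 6.0),
    ]


@dataclass
class GaitSimConfig:
    fs: float = 100.0
    schedule: list[tuple[str, float]] = field(default_factory=default_schedule)
    mode_params: dict[str, ModeParams] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PARAMS)
    )
    noise_sd: tuple[float, float, float] = (0.003, 0.02, 0.03)
    hip_offset: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for mode, dur in self.schedule:
            if dur <= 0:
                raise ValueError(f"schedule duration for {mode!r} must be > 0")
            if mode not in self.mode_params:
                raise ValueError(f"schedule mode {mode!r} has no parameters")
        walking = [
            p.cadence_hz for m, p in self.mode_params.items() if p.cadence_hz > 0
        ]
        if len(set(walking)) != len(walking):
            raise ValueError("walking-mode cadences must be distinct")


def simulate_gait_recording(config: GaitSimConfig) -> RawRecording:
    """Three quasi-periodic channels whose cadence/amplitude depend on mode.

    Hip position oscillates slightly around a positive offset (it never
    crosses zero), thigh angle is a cadence sinusoid, and thigh moment is a
    phase-shifted sinusoid plus sharpened impulses at each stride.  Standing
    segments are near-constant noise.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for mode, duration in config.schedule:
        n = int(round(duration * config.fs))
        t = np.arange(n) / config.fs
        params = config.mode_params[mode]
        cad, (a_hip, a_ang, a_mom) = params.cadence_hz, params.amplitudes
        if cad > 0:
            phase = 2.0 * np.pi * cad * t
            hip = config.hip_offset + a_hip * np.sin(2.0 * phase)
            ang = a_ang * np.sin(phase)
            mom = a_mom * np.sin(phase + np.pi / 4) + 0.5 * a_mom * np.maximum(
                0.0, np.sin(phase)
            ) ** 8
        else:
            hip = np.full(n, config.hip_offset)
            ang = np.zeros(n)
            mom = np.zeros(n)
        seg = np.column_stack([hip, ang, mom])
        seg += rng.normal(0.0, config.noise_sd, size=seg.shape)
        chunks.append(seg)
        labels.append(np.full(n, mode, dtype=object))
    return RawRecording(
        samples=np.concatenate(chunks, axis=0),
        fs=config.fs,
        labels=np.concatenate(labels),
        channel_names=CHANNEL_NAMES,
    )


@dataclass
class PlantedTableConfig:
    """Labeled table with a known informative subset among noise columns."""

    m: int = 200
    n: int = 30
    informative: tuple[int, ...] = (0, 1, 2, 3, 4)
    classes: int = 2
    effect_size: float = 3.0
    redundancy: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not all(0 <= i < self.n for i in self.informative):
            raise ValueError("informative indices out of range")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        for copy_idx, source_idx, rho in self.redundancy:
            if not (0 <= copy_idx < self.n and 0 <= source_idx < self.n):
                raise ValueError("redundancy indices out of range")
            if copy_idx in self.informative:
                raise ValueError("a redundant copy cannot be an informative column")
            if not -1.0 <= rho <= 1.0:
                raise ValueError("redundancy correlation must be in [-1, 1]")


def generate_planted_table(config: PlantedTableConfig) -> FeatureTable:
    """Gaussian table: informative columns get class-dependent means spaced
    ``effect_size`` noise-sds apart; the rest are pure noise; redundant
    columns are noisy standardized copies at the configured correlation."""
    rng = np.random.default_rng(config.seed)
    k = config.classes
    counts = [config.m // k + (1 if i < config.m % k else 0) for i in range(k)]
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    rng.shuffle(y)
    X = rng.normal(size=(config.m, config.n))
    centered = (np.arange(k) - (k - 1) / 2.0) * config.effect_size
    for j in config.informative:
        X[:, j] += centered[y]
    for copy_idx, source_idx, rho in config.redundancy:
        src = X[:, source_idx]
        z = (src - src.mean()) / src.std()
        X[:, copy_idx] = rho * z + np.sqrt(1.0 - rho**2) * rng.normal(
            size=config.m
        )
    return FeatureTable(values=X, labels=y, layout=None)
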