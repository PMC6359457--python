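"""Time- and frequency-domain frame features and training-table assembly.

Feature definitions follow the canonical surface-EMG feature set: threshold
counters (ZC, SSC, WAMP), waveform statistics (WL, VAR, MAV, MAV1, MAV2,
RMS, SK, KU), pairwise frame similarity (COR, ANG), and periodogram /
autoregressive spectral summaries (MNF, MDF, MAXF, AR4).  Variance, skewness
and kurtosis use the population convention (divide by the frame length)
throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import periodogram
from statsmodels.regression.linear_model import burg as _burg
from statsmodels.regression.linear_model import yule_walker as _yule_walker

from .windowing import Frame

logger = logging.getLogger(__name__)

__all__ = [
    "TD_TYPES",
    "FD_TYPES",
    "PAIR_TYPES",
    "ALL_TYPES",
    "LayoutEntry",
    "FeatureLayout",
    "FeatureConfig",
    "FeatureTable",
    "full_layout",
    "preselected_layout",
    "compute_td_features",
    "compute_pair_features",
    "compute_fd_features",
    "build_feature_table",
    "normalize_table",
]

#: Per-channel time-domain scalar types.
TD_TYPES = (
    "SSC", "ZC", "WL", "VAR", "MAV", "MAV1", "MAV2", "RMS", "WAMP", "SK", "KU",
)
#: Per-channel frequency-domain types (AR4 expands to 4 columns).
FD_TYPES = ("MDF", "MNF", "MAXF", "AR4")
#: Channel-pair types.
PAIR_TYPES = ("COR", "ANG")
ALL_TYPES = TD_TYPES + FD_TYPES + PAIR_TYPES


@dataclass(frozen=True)
class LayoutEntry:
    """One layout item: a feature type and its channel (or channel-pair) target."""

    feature_type: str
    target: int | tuple[int, int]

    def __post_init__(self) -> None:
        if self.feature_type not in ALL_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.feature_type in PAIR_TYPES:
            if not (isinstance(self.target, tuple) and len(self.target) == 2):
                raise ValueError(f"{self.feature_type} needs a channel pair")
            a, b = self.target
            if a == b:
                raise ValueError("pair features need two distinct channels")
            # unordered pair: canonicalize
            object.__setattr__(self, "target", (min(a, b), max(a, b)))
        elif not isinstance(self.target, (int, np.integer)):
            raise ValueError(f"{self.feature_type} needs a single channel index")

    @property
    def n_columns(self) -> int:
        return 4 if self.feature_type == "AR4" else 1

    def column_names(self, channel_names: Sequence[str] | None = None) -> list[str]:
        def cname(i: int) -> str:
            return channel_names[i] if channel_names else str(i)

        if self.feature_type in PAIR_TYPES:
            a, b = self.target  # type: ignore[misc]
            return [f"{self.feature_type}@{cname(a)}-{cname(b)}"]
        if self.feature_type == "AR4":
            return [f"AR4.{k}@{cname(self.target)}" for k in range(1, 5)]
        return [f"{self.feature_type}@{cname(self.target)}"]


@dataclass
class FeatureLayout:
    """Ordered list of layout entries describing the columns of a table."""

    entries: list[LayoutEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.feature_type, e.target)
            if key in seen:
                raise ValueError(f"duplicate layout entry {key}")
            seen.add(key)

    @property
    def n_columns(self) -> int:
        return sum(e.n_columns for e in self.entries)

    def column_names(self, channel_names: Sequence[str] | None = None) -> list[str]:
        names: list[str] = []
        for e in self.entries:
            names.extend(e.column_names(channel_names))
        return names

    def max_channel(self) -> int:
        chans: list[int] = []
        for e in self.entries:
            if isinstance(e.target, tuple):
                chans.extend(e.target)
            else:
                chans.append(int(e.target))
        return max(chans)

    def without(self, feature_type: str, target) -> "FeatureLayout":
        """Copy of the layout with one (type, target) entry removed."""
        if isinstance(target, tuple):
            target = (min(target), max(target))
        kept = [
            e
            for e in self.entries
            if not (e.feature_type == feature_type and e.target == target)
        ]
        if len(kept) == len(self.entries):
            raise KeyError(f"layout has no entry ({feature_type}, {target})")
        return FeatureLayout(kept)


def full_layout(n_channels: int = 3) -> FeatureLayout:
    """All feature types: 14 scalars per channel, COR/ANG per pair, AR4 per channel."""
    entries = [
        LayoutEntry(t, c)
        for c in range(n_channels)
        for t in TD_TYPES + ("MDF", "MNF", "MAXF")
    ]
    entries += [
        LayoutEntry(t, (a, b))
        for t in PAIR_TYPES
        for a in range(n_channels)
        for b in range(a + 1, n_channels)
    ]
    entries += [LayoutEntry("AR4", c) for c in range(n_channels)]
    return FeatureLayout(entries)


#: Scalar types surviving the pre-selection step (MAV1/MAV2 and the
#: periodogram frequency summaries are dropped).
PRESELECTED_SCALAR_TYPES = (
    "SSC", "ZC", "WL", "VAR", "MAV", "RMS", "WAMP", "SK", "KU",
)


def preselected_layout(n_channels: int = 3) -> FeatureLayout:
    """The 12 pre-selected types: 9 scalars + COR + ANG + AR4."""
    entries = [
        LayoutEntry(t, c) for c in range(n_channels) for t in PRESELECTED_SCALAR_TYPES
    ]
    entries += [
        LayoutEntry(t, (a, b))
        for t in PAIR_TYPES
        for a in range(n_channels)
        for b in range(a + 1, n_channels)
    ]
    entries += [LayoutEntry("AR4", c) for c in range(n_channels)]
    return FeatureLayout(entries)


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and spectral-estimation settings.

    ``threshold_scale='train_std'`` interprets the three thresholds as
    multiples of the per-channel standard deviation over the frames being
    tabulated (resolved by :func:`build_feature_table`); ``'absolute'`` uses
    them as raw amplitudes.
    """

    zc_threshold: float = 0.01
    ssc_threshold: float = 0.01
    wamp_threshold: float = 0.01
    threshold_scale: str = "train_std"
    ar_order: int = 4
    ar_method: str = "yule_walker"
    psd_window: str = "rectangular"

    def __post_init__(self) -> None:
        for name in ("zc_threshold", "ssc_threshold", "wamp_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.threshold_scale not in ("absolute", "train_std"):
            raise ValueError(f"unknown threshold_scale {self.threshold_scale!r}")
        if self.ar_method not in ("yule_walker", "burg"):
            raise ValueError(f"unknown ar_method {self.ar_method!r}")
        if self.psd_window not in ("rectangular", "hamming"):
            raise ValueError(f"unknown psd_window {self.psd_window!r}")

    @classmethod
    def absolute(cls, threshold: float = 0.0, **kwargs) -> "FeatureConfig":
        """Convenience: all three thresholds fixed at an absolute amplitude."""
        return cls(
            zc_threshold=threshold,
            ssc_threshold=threshold,
            wamp_threshold=threshold,
            threshold_scale="absolute",
            **kwargs,
        )

    def resolved(self, channel_std: float) -> "FeatureConfig":
        """Absolute-threshold copy for one channel's standard deviation."""
        if self.threshold_scale == "absolute":
            return self
        return replace(
            self,
            zc_threshold=self.zc_threshold * channel_std,
            ssc_threshold=self.ssc_threshold * channel_std,
            wamp_threshold=self.wamp_threshold * channel_std,
            threshold_scale="absolute",
        )


@dataclass
class FeatureTable:
    """m patterns x n features with labels and an optional column layout."""

    values: np.ndarray
    labels: np.ndarray
    layout: FeatureLayout | None = None
    normalized: bool = False
    channel_names: tuple[str, ...] | None = None
    column_means: np.ndarray | None = None
    column_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if self.layout is not None and self.layout.n_columns != self.values.shape[1]:
            raise ValueError(
                f"layout expands to {self.layout.n_columns} columns but values "
                f"have {self.values.shape[1]}"
            )

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list[str]:
        if self.layout is not None:
            return self.layout.column_names(self.channel_names)
        return [f"f{i}" for i in range(self.n_features)]

    def apply_normalization(self, values: np.ndarray) -> np.ndarray:
        """Apply this table's stored scaling to held-out rows."""
        if self.column_means is None or self.column_scales is None:
            raise ValueError("table carries no normalization parameters")
        return (np.asarray(values, dtype=float) - self.column_means) / self.column_scales

    def select_columns(self, indices: Sequence[int]) -> "FeatureTable":
        """Sub-table with the given columns (layout dropped)."""
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            layout=None,
            normalized=self.normalized,
        )


# ---------------------------------------------------------------------------
# per-frame feature computations


def _require_absolute(config: FeatureConfig) -> None:
    if config.threshold_scale != "absolute":
        raise ValueError(
            "thresholds are std-relative; resolve them first "
            "(FeatureConfig.resolved) or use FeatureConfig.absolute()"
        )


def _zero_variance_moment(name: str) -> float:
    logger.warning("%s requested on a zero-variance frame; returning 0", name)
    return 0.0


def compute_td_features(
    x: np.ndarray, types: Sequence[str], config: FeatureConfig
) -> np.ndarray:
    """Time-domain features of a single channel's frame, one value per type."""
    _require_absolute(config)
    x = np.asarray(x, dtype=float)
    n = len(x)
    diffs = np.diff(x)
    out = np.empty(len(types))
    for k, t in enumerate(types):
        if t == "SSC":
            if n < 3:
                raise ValueError("SSC needs a frame of length >= 3")
            prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
            out[k] = np.count_nonzero(prod > config.ssc_threshold)
        elif t == "ZC":
            if n < 2:
                raise ValueError("ZC needs a frame of length >= 2")
            sign_change = x[:-1] * x[1:] < 0
            big_enough = np.abs(diffs) >= config.zc_threshold
            out[k] = np.count_nonzero(sign_change & big_enough)
        elif t == "WL":
            if n < 2:
                raise ValueError("WL needs a frame of length >= 2")
            out[k] = np.sum(np.abs(diffs))
        elif t == "VAR":
            out[k] = np.var(x)
        elif t == "MAV":
            out[k] = np.mean(np.abs(x))
        elif t in ("MAV1", "MAV2"):
            out[k] = _weighted_mav(x, t)
        elif t == "RMS":
            out[k] = np.sqrt(np.mean(x**2))
        elif t == "WAMP":
            out[k] = np.count_nonzero(np.abs(diffs) > config.wamp_threshold)
        elif t in ("SK", "KU"):
            sd = np.std(x)
            # roundoff guard: a constant frame can leave sd ~ 1e-16
            if sd <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
                out[k] = _zero_variance_moment(t)
            else:
                z = (x - np.mean(x)) / sd
                out[k] = np.mean(z**3) if t == "SK" else np.mean(z**4)
        else:
            raise ValueError(f"{t!r} is not a time-domain type")
    return out


def _weighted_mav(x: np.ndarray, variant: str) -> float:
    """Piecewise-weighted mean absolute value (MAV1/MAV2), 1-indexed windows."""
    n = len(x)
    i = np.arange(1, n + 1, dtype=float)
    core = (i >= 0.25 * n) & (i <= 0.75 * n)
    w = np.ones(n)
    if variant == "MAV1":
        w[~core] = 0.5
    else:  # MAV2: linear ramps outside the core window
        lo = i < 0.25 * n
        hi = i > 0.75 * n
        w[lo] = 4.0 * i[lo] / n
        w[hi] = 4.0 * (n - i[hi]) / n
    return float(np.mean(w * np.abs(x)))


def compute_pair_features(
    frame_a: np.ndarray, frame_b: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation and inter-frame angle (radians) of two raw frames."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("pair features need two equal-length vectors (>= 2)")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("ANG is undefined for a zero-norm frame")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("COR is undefined for a zero-variance frame")
    cor = float(np.corrcoef(a, b)[0, 1])
    ang = float(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))
    return cor, ang


def compute_fd_features(
    x: np.ndarray, fs: float, types: Sequence[str], config: FeatureConfig
) -> np.ndarray:
    """Frequency-domain features of a frame (AR4 contributes 4 values)."""
    x = np.asarray(x, dtype=float)
    needs_psd = any(t in ("MNF", "MDF", "MAXF") for t in types)
    if needs_psd:
        window = "boxcar" if config.psd_window == "rectangular" else "hamming"
        freqs, power = periodogram(x, fs=fs, window=window)
        total = power.sum()
        if total == 0:
            raise ValueError("spectral features undefined for an all-zero frame")
    out: list[float] = []
    for t in types:
        if t == "MNF":
            out.append(float(np.sum(freqs * power) / total))
        elif t == "MDF":
            csum = np.cumsum(power)
            out.append(float(freqs[np.searchsorted(csum, total / 2.0)]))
        elif t == "MAXF":
            out.append(float(freqs[np.argmax(power)]))
        elif t == "AR4":
            out.extend(_ar_coefficients(x, config))
        else:
            raise ValueError(f"{t!r} is not a frequency-domain type")
    return np.array(out)


def _ar_coefficients(x: np.ndarray, config: FeatureConfig) -> np.ndarray:
    order = config.ar_order
    if len(x) < 2 * order:
        raise ValueError(f"AR order {order} needs a frame of length >= {2 * order}")
    if np.std(x) == 0:
        raise ValueError("AR coefficients undefined for a constant frame")
    if config.ar_method == "burg":
        rho, _ = _burg(x, order=order, demean=True)
    else:
        rho, _ = _yule_walker(x, order=order, method="mle", demean=True)
    return np.asarray(rho, dtype=float)


# ---------------------------------------------------------------------------
# table assembly and normalization


def build_feature_table(
    frames: Sequence[Frame],
    layout: FeatureLayout,
    config: FeatureConfig | None = None,
    fs: float = 100.0,
    channel_names: Sequence[str] | None = None,
) -> FeatureTable:
    """Row k is frame k's features concatenated in layout order."""
    if not frames:
        raise ValueError("cannot build a feature table from zero frames")
    config = config or FeatureConfig()
    n_channels = frames[0].n_channels
    if layout.max_channel() >= n_channels:
        raise ValueError(
            f"layout references channel {layout.max_channel()} but frames "
            f"have only {n_channels} channels"
        )
    # std-relative thresholds resolve against the pooled per-channel std
    stacked = np.concatenate([f.data for f in frames], axis=0)
    channel_configs = [
        config.resolved(float(np.std(stacked[:, c]))) for c in range(n_channels)
    ]
    rows = np.empty((len(frames), layout.n_columns))
    for r, frame in enumerate(frames):
        col = 0
        for entry in layout.entries:
            t = entry.feature_type
            if t in PAIR_TYPES:
                a, b = entry.target  # type: ignore[misc]
                cor, ang = compute_pair_features(frame.data[:, a], frame.data[:, b])
                rows[r, col] = cor if t == "COR" else ang
                col += 1
            elif t in TD_TYPES:
                c = int(entry.target)  # type: ignore[arg-type]
                rows[r, col] = compute_td_features(
                    frame.data[:, c], [t], channel_configs[c]
                )[0]
                col += 1
            else:  # FD
                c = int(entry.target)  # type: ignore[arg-type]
                vals = compute_fd_features(
                    frame.data[:, c], fs, [t], channel_configs[c]
                )
                rows[r, col : col + entry.n_columns] = vals
                col += entry.n_columns
    labels = np.array([f.label for f in frames])
    return FeatureTable(
        values=rows,
        labels=labels,
        layout=layout,
        channel_names=tuple(channel_names) if channel_names else None,
    )


def drop_zero_variance_columns(
    table: FeatureTable,
) -> tuple[FeatureTable, list[str]]:
    """Remove constant columns (they carry no signal and break normalization).

    Returns the reduced table (layout dropped unless every removed column is
    a scalar entry) and the removed column names.
    """
    scales = table.values.std(axis=0)
    keep = np.nonzero(scales > 0)[0]
    names = table.column_names()
    dropped = [names[i] for i in np.nonzero(scales == 0)[0]]
    if not dropped:
        return table, []
    logger.info("dropping zero-variance columns: %s", dropped)
    return (
        FeatureTable(
            values=table.values[:, keep],
            labels=table.labels.copy(),
            layout=None,
            normalized=table.normalized,
        ),
        dropped,
    )


def normalize_table(table: FeatureTable) -> FeatureTable:
    """Standardize columns to zero mean / unit population variance.

    The fitted means and scales are stored on the result so the identical
    transform can be applied to held-out rows.
    """
    means = table.values.mean(axis=0)
    scales = table.values.std(axis=0)  # population convention
    bad = np.nonzero(scales == 0)[0]
    if bad.size:
        names = table.column_names()
        raise ValueError(
            f"zero-variance column(s): {[names[i] for i in bad]}"
        )
    return FeatureTable(
        values=(table.values - means) / scales,
        labels=table.labels.copy(),
        layout=table.layout,
        normalized=True,
        channel_names=table.channel_names,
        column_means=means,
        column_scales=scales,
    )
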