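"""Cross-validation protocols, classifier plumbing, majority-vote label
smoothing, and the real-time feasibility check.

Classifiers are consumed through the scikit-learn fit/predict contract and
never reimplemented here.  Normalization is fitted on each training split by
default (``normalize_scope='train_only'``); ``'global'`` standardizes the
whole table once, matching the original whole-set convention.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import wilcoxon
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable
from .windowing import WindowingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CvScheme",
    "CvResult",
    "MvfConfig",
    "LabelStream",
    "FeasibilityReport",
    "make_classifier",
    "crossval_error",
    "majority_vote_filter",
    "realtime_feasible",
    "compare_paired_scores",
]

#: Hidden-node grid searched when tuning the standard MLP classifier.
MLP_HIDDEN_GRID = (3, 4, 5, 6, 8, 10, 15, 20)

REALTIME_LIMIT_MS = 300.0


def make_classifier(name: str, *, sigma: float = 1.0, hidden_nodes: int = 10,
                    seed: int | None = None):
    """Factory over the supported classifier names.

    ``sigma`` is the RBF kernel width (mapped to ``gamma = 1 / (2 sigma^2)``).
    """
    name = name.lower().replace("_", "-")
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "qda":
        return QuadraticDiscriminantAnalysis()
    if name == "svm-linear":
        return SVC(kernel="linear", decision_function_shape="ovo")
    if name == "svm-rbf":
        return SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma**2),
                   decision_function_shape="ovo")
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(hidden_nodes,),
            max_iter=500,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class CvScheme:
    """Random stratified c-fold or leave-one-sequence-out splitting."""

    kind: str = "random_kfold"
    folds: int = 10
    sequence_ids: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("random_kfold", "leave_one_sequence_out"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "random_kfold" and self.folds < 2:
            raise ValueError("random k-fold needs folds >= 2")
        if self.kind == "leave_one_sequence_out" and self.sequence_ids is None:
            raise ValueError("leave-one-sequence-out needs sequence_ids")

    def split(self, labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_idx, test_idx) pairs; every pattern is tested exactly once."""
        n = len(labels)
        if self.kind == "random_kfold":
            splitter = StratifiedKFold(
                n_splits=self.folds, shuffle=True, random_state=self.seed
            )
            return [
                (tr, te) for tr, te in splitter.split(np.zeros(n), labels)
            ]
        seq = np.asarray(self.sequence_ids)
        if len(seq) != n:
            raise ValueError("sequence_ids length must match pattern count")
        out = []
        for sid in np.unique(seq):
            test = np.nonzero(seq == sid)[0]
            train = np.nonzero(seq != sid)[0]
            out.append((train, test))
        return out


@dataclass
class CvResult:
    mean_error: float
    fold_errors: list[float]
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return 1.0 - self.mean_error


def crossval_error(
    table: FeatureTable,
    classifier,
    scheme: CvScheme,
    normalize_scope: str = "train_only",
) -> CvResult:
    """Mean misclassification fraction over CV folds.

    Folds whose training split is missing a class are flagged and excluded
    from the mean.  ``normalize_scope='train_only'`` standardizes each fold
    with statistics of its own training rows; ``'global'`` standardizes the
    whole table once; ``'none'`` leaves values untouched.
    """
    X, y = table.values, table.labels
    all_classes = np.unique(y)
    if len(all_classes) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    if normalize_scope not in ("train_only", "global", "none"):
        raise ValueError(f"unknown normalize_scope {normalize_scope!r}")
    if normalize_scope == "global":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    fold_errors: list[float] = []
    flagged: list[int] = []
    for k, (train, test) in enumerate(scheme.split(y)):
        if len(np.unique(y[train])) < len(all_classes):
            logger.warning("fold %d training split is missing a class; flagged", k)
            flagged.append(k)
            continue
        Xtr, Xte = X[train], X[test]
        if normalize_scope == "train_only":
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        model = clone(classifier)
        model.fit(Xtr, y[train])
        pred = model.predict(Xte)
        fold_errors.append(float(np.mean(pred != y[test])))
    if not fold_errors:
        raise ValueError("every fold was flagged; cannot compute a CV error")
    return CvResult(
        mean_error=float(np.mean(fold_errors)),
        fold_errors=fold_errors,
        flagged_folds=flagged,
    )


# ---------------------------------------------------------------------------
# majority-vote filtering and the real-time constraint


@dataclass(frozen=True)
class MvfConfig:
    """Half-window q; the filter spans 2q+1 consecutive classifications."""

    q: int = 5
    increment_ms: float | None = None
    frame_ms: float | None = None

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be >= 0")

    @property
    def window_length(self) -> int:
        return 2 * self.q + 1


@dataclass
class LabelStream:
    """Time-ordered classified gait modes emitted every ``step_ms``."""

    labels: list
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not len(self.labels):
            raise ValueError("a label stream cannot be empty")
        self.labels = list(self.labels)


def majority_vote_filter(stream: LabelStream, config: MvfConfig) -> LabelStream:
    """Most frequent label in the centered (2q+1)-window around each index.

    The window shrinks at the stream edges.  Ties are broken by the previous
    filtered output (the raw label at the stream start).  Output length
    equals input length.
    """
    labels = stream.labels
    q = config.q
    out: list = []
    for i in range(len(labels)):
        window = labels[max(0, i - q) : i + q + 1]
        counts = Counter(window)
        best = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == best]
        if len(tied) == 1:
            out.append(tied[0])
        elif out:
            out.append(out[-1])
        else:
            out.append(labels[i])
    return LabelStream(labels=out, step_ms=stream.step_ms)


@dataclass
class FeasibilityReport:
    feasible: bool
    delay_ms: float
    limit_ms: float = REALTIME_LIMIT_MS

    def __str__(self) -> str:
        verdict = "feasible" if self.feasible else "INFEASIBLE"
        return (
            f"majority-vote delay {self.delay_ms:g} ms vs limit "
            f"{self.limit_ms:g} ms: {verdict}"
        )


def realtime_feasible(
    windowing: WindowingConfig, mvf: MvfConfig
) -> FeasibilityReport:
    """Check the q-step output delay against the 300 ms responsiveness limit.

    Disjoint windowing emits a label every ``Lf`` ms (delay ``q * Lf``);
    overlapped windowing emits every ``I`` ms (delay ``q * I``).
    """
    step = (
        windowing.frame_ms
        if windowing.mode == "disjoint"
        else float(windowing.increment_ms)  # type: ignore[arg-type]
    )
    delay = mvf.q * step
    return FeasibilityReport(feasible=delay <= REALTIME_LIMIT_MS, delay_ms=delay)


def compare_paired_scores(a: Sequence[float], b: Sequence[float]):
    """Wilcoxon signed-rank comparison of two paired score sequences.

    Thin reporting helper over :func:`scipy.stats.wilcoxon`.
    """
    return wilcoxon(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
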