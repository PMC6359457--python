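"""Gradient-based multi-objective feature selection.

A single-hidden-layer sigmoid MLP is trained with per-feature input
multipliers ``beta`` in [0, 1] under an elastic-net penalty
``lambda * sum(alpha * beta^2 + (1 - alpha) * |beta|)`` added to half the
summed squared output error.  Hidden and output weights are box-bounded so a
shrunken multiplier cannot be silently compensated by large weights.  After
training, features are ranked by ``beta`` and the smallest prefix holding at
least a ``theta`` fraction of the total multiplier mass is selected.
Sweeping ``lambda`` over a grid yields one subset per grid point; scoring
each subset by (size, CV error) and keeping the non-dominated records gives
the Pareto front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .evaluation import CvScheme, crossval_error, make_classifier
from .features import FeatureTable
from .pareto import ParetoArchive, ParetoPoint, extract_pareto

logger = logging.getLogger(__name__)

__all__ = [
    "GmofsConfig",
    "GmofsModel",
    "LambdaRecord",
    "GmofsResult",
    "default_lambda_grid",
    "parse_lambda_grid",
    "forward",
    "cost",
    "gradients",
    "initialize_model",
    "train_constrained",
    "select_significant",
    "one_hot_targets",
    "run_gmofs",
    "make_cv_evaluator",
    "make_mlp_subset_evaluator",
]


def default_lambda_grid() -> np.ndarray:
    """Increment 1 on [0, 30], increment 10 on (30, 150] — 43 values."""
    return np.concatenate([np.arange(0, 31, 1.0), np.arange(40, 151, 10.0)])


def parse_lambda_grid(spec: str) -> np.ndarray:
    """Parse ``"start:step:stop,..."`` segments (stops inclusive)."""
    values: list[np.ndarray] = []
    for part in spec.split(","):
        pieces = part.strip().split(":")
        if len(pieces) == 1:
            values.append(np.array([float(pieces[0])]))
        elif len(pieces) == 3:
            start, step, stop = map(float, pieces)
            if step <= 0:
                raise ValueError(f"grid step must be positive in {part!r}")
            values.append(np.arange(start, stop + step / 2.0, step))
        else:
            raise ValueError(f"cannot parse grid segment {part!r}")
    grid = np.concatenate(values)
    if np.any(grid < 0):
        raise ValueError("lambda values must be >= 0")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be non-decreasing")
    return grid


@dataclass
class GmofsConfig:
    hidden_nodes: int = 5  # p, including the bias node
    alpha: float = 0.0
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    weight_bound_a: float = 5.0  # |w_hj| <= a (hidden -> output)
    weight_bound_b: float = 5.0  # |v_ih| <= b (input -> hidden)
    threshold: float = 0.95
    max_iter: int = 100
    tol_x: float = 1e-3
    tol_fun: float = 1e-3
    target_low: float = 0.05
    target_high: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.size == 0:
            raise ValueError("lambda grid must be non-empty")
        if np.any(np.diff(self.lambda_grid) < 0):
            raise ValueError("lambda grid must be non-decreasing")
        if np.any(self.lambda_grid < 0):
            raise ValueError("lambda values must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.hidden_nodes < 2:
            raise ValueError("need at least 2 hidden nodes (one is the bias)")
        if self.weight_bound_a <= 0 or self.weight_bound_b <= 0:
            raise ValueError("weight bounds must be positive")


@dataclass
class GmofsModel:
    """Input multipliers plus bounded hidden/output weights.

    ``V`` has shape (n + 1, p - 1): the scaled inputs plus an input bias
    feed the p - 1 free hidden nodes; the p-th hidden node is the bias fixed
    at 1.  ``W`` has shape (p, K).
    """

    beta: np.ndarray
    V: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        n, p, _ = self.n_inputs, self.n_hidden, self.n_outputs
        if self.V.shape != (n + 1, p - 1):
            raise ValueError(
                f"V must be ({n + 1}, {p - 1}), got {self.V.shape}"
            )

    @property
    def n_inputs(self) -> int:
        return len(self.beta)

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]  # includes the bias node

    @property
    def n_outputs(self) -> int:
        return self.W.shape[1]

    def check_bounds(self, a: float, b: float, atol: float = 1e-8) -> bool:
        return bool(
            np.all(self.beta >= -atol)
            and np.all(self.beta <= 1 + atol)
            and np.all(np.abs(self.W) <= a + atol)
            and np.all(np.abs(self.V) <= b + atol)
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _hidden_and_output(
    model: GmofsModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (Z_bias, H, O): biased scaled inputs, free hidden activations,
    and outputs, all row-per-pattern."""
    m = X.shape[0]
    Z = X * model.beta
    Zb = np.hstack([Z, np.ones((m, 1))])
    H = _sigmoid(Zb @ model.V)  # (m, p - 1)
    Hb = np.hstack([H, np.ones((m, 1))])  # bias hidden node fixed at 1
    O = _sigmoid(Hb @ model.W)
    return Zb, H, O


def forward(model: GmofsModel, x: np.ndarray) -> np.ndarray:
    """Network outputs in (0, 1)^K for one pattern or a batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} inputs, got {X.shape[1]}"
        )
    _, _, O = _hidden_and_output(model, X)
    return O[0] if single else O


def _penalty(beta: np.ndarray, lam: float, alpha: float) -> float:
    return lam * float(np.sum(alpha * beta**2 + (1 - alpha) * np.abs(beta)))


def cost(
    model: GmofsModel, X: np.ndarray, T: np.ndarray, lam: float, alpha: float
) -> float:
    """Half the summed squared output error plus the elastic-net beta penalty."""
    _, _, O = _hidden_and_output(model, X)
    err = 0.5 * float(np.sum((T - O) ** 2))
    return err + _penalty(model.beta, lam, alpha)


def gradients(
    model: GmofsModel, X: np.ndarray, T: np.ndarray, lam: float, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic (dJ/dbeta, dJ/dV, dJ/dW).

    Output deltas use the sigmoid derivative in the actual output,
    ``delta = (o - t) * o * (1 - o)``.  The L1 subgradient at beta = 0 is 0,
    so inactive features stay inactive.
    """
    Zb, H, O = _hidden_and_output(model, X)
    Hb = np.hstack([H, np.ones((X.shape[0], 1))])
    delta = (O - T) * O * (1.0 - O)  # (m, K)
    dW = Hb.T @ delta  # (p, K)
    # back through the free (non-bias) hidden nodes
    G = (delta @ model.W[:-1, :].T) * H * (1.0 - H)  # (m, p - 1)
    dV = Zb.T @ G  # (n + 1, p - 1)
    dbeta = np.sum((G @ model.V[:-1, :].T) * X, axis=0)
    dbeta += lam * (2.0 * alpha * model.beta + (1 - alpha) * np.sign(model.beta))
    return dbeta, dV, dW


def initialize_model(
    n: int, p: int, k: int, config: GmofsConfig, rng: np.random.Generator
) -> GmofsModel:
    """Seeded start: beta uniform in [0.4, 0.6], weights within 10% of bounds."""
    beta = rng.uniform(0.4, 0.6, size=n)
    V = rng.uniform(-0.1, 0.1, size=(n + 1, p - 1)) * config.weight_bound_b
    W = rng.uniform(-0.1, 0.1, size=(p, k)) * config.weight_bound_a
    return GmofsModel(beta=beta, V=V, W=W)


@dataclass
class TrainResult:
    model: GmofsModel
    initial_cost: float
    final_cost: float
    n_iterations: int
    decreased: bool
    message: str = ""


def _pack(model: GmofsModel) -> np.ndarray:
    return np.concatenate([model.beta, model.V.ravel(), model.W.ravel()])


def _unpack(theta: np.ndarray, n: int, p: int, k: int) -> GmofsModel:
    nb = n
    nv = (n + 1) * (p - 1)
    beta = theta[:nb]
    V = theta[nb : nb + nv].reshape(n + 1, p - 1)
    W = theta[nb + nv :].reshape(p, k)
    return GmofsModel(beta=beta, V=V, W=W)


def train_constrained(
    X: np.ndarray,
    T: np.ndarray,
    lam: float,
    config: GmofsConfig,
    rng: np.random.Generator | None = None,
    init: GmofsModel | None = None,
) -> TrainResult:
    """Bound-constrained minimization of the penalized cost (L-BFGS-B).

    Box bounds: beta in [0, 1], |V| <= b, |W| <= a.  The returned cost never
    exceeds the initialization cost; failure to decrease is flagged on the
    result, never silent.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    m, n = X.shape
    k = T.shape[1]
    p = config.hidden_nodes
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model0 = init if init is not None else initialize_model(n, p, k, config, rng)
    theta0 = _pack(model0)
    j0 = cost(model0, X, T, lam, config.alpha)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        mdl = _unpack(theta, n, p, k)
        db, dv, dw = gradients(mdl, X, T, lam, config.alpha)
        j = cost(mdl, X, T, lam, config.alpha)
        return j, np.concatenate([db, dv.ravel(), dw.ravel()])

    bounds = (
        [(0.0, 1.0)] * n
        + [(-config.weight_bound_b, config.weight_bound_b)] * ((n + 1) * (p - 1))
        + [(-config.weight_bound_a, config.weight_bound_a)] * (p * k)
    )
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.max_iter, "ftol": config.tol_fun * 1e-3},
    )
    model = _unpack(res.x, n, p, k)
    j1 = cost(model, X, T, lam, config.alpha)
    decreased = j1 <= j0 + 1e-12
    if not decreased:
        logger.warning(
            "optimizer failed to decrease the cost (J0=%.6g, J1=%.6g)", j0, j1
        )
        model, j1 = model0, j0
    return TrainResult(
        model=model,
        initial_cost=j0,
        final_cost=j1,
        n_iterations=int(res.nit),
        decreased=decreased,
        message=str(res.message),
    )


def select_significant(beta: np.ndarray, theta: float = 0.95) -> np.ndarray:
    """Indices of the r largest multipliers whose mass fraction reaches theta.

    r is the smallest count with ``sum(beta sorted desc)[:r] / sum(beta) >=
    theta``; ties in beta are broken toward the lower original index.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")
    total = beta.sum()
    if total == 0:
        raise ValueError("all multipliers are zero; nothing to rank")
    order = np.argsort(-beta, kind="stable")
    frac = np.cumsum(beta[order]) / total
    r = int(np.searchsorted(frac, theta - 1e-12) + 1)
    return order[:r]


def one_hot_targets(
    labels: np.ndarray,
    classes: Sequence | None = None,
    low: float = 0.05,
    high: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft one-hot targets (low/high instead of 0/1 keeps sigmoids reachable)."""
    labels = np.asarray(labels)
    cls = np.asarray(classes) if classes is not None else np.unique(labels)
    T = np.full((len(labels), len(cls)), low)
    for j, c in enumerate(cls):
        T[labels == c, j] = high
    return T, cls


@dataclass
class LambdaRecord:
    lam: float
    beta: np.ndarray
    subset: np.ndarray  # feature indices ordered by descending beta
    f1: float | None = None  # subset size
    f2: float | None = None  # CV error
    flagged: bool = False
    note: str = ""


@dataclass
class GmofsResult:
    records: list[LambdaRecord]
    pareto_front: ParetoArchive
    n_trainings: int

    @property
    def pareto_set(self) -> list[LambdaRecord]:
        return [p.payload for p in self.pareto_front.points]


def run_gmofs(
    X: np.ndarray,
    T: np.ndarray,
    config: GmofsConfig,
    evaluator: Callable[[np.ndarray], float],
) -> GmofsResult:
    """The full lambda sweep.

    Per grid point: train the constrained network, select the significant
    subset, then score every subset with the evaluator callback
    (subset indices -> CV error fraction) and keep the non-dominated
    (size, error) records as the Pareto front.  Evaluator failures flag the
    record and exclude it from the front.
    """
    rng = np.random.default_rng(config.seed)
    records: list[LambdaRecord] = []
    n_trainings = 0
    for lam in config.lambda_grid:
        child = np.random.default_rng(rng.integers(2**63))
        result = train_constrained(X, T, float(lam), config, rng=child)
        n_trainings += 1
        beta = result.model.beta
        try:
            subset = select_significant(beta, config.threshold)
            rec = LambdaRecord(lam=float(lam), beta=beta, subset=subset)
            if not result.decreased:
                rec.note = "optimizer failed to decrease the cost"
        except ValueError as exc:
            rec = LambdaRecord(
                lam=float(lam),
                beta=beta,
                subset=np.array([], dtype=int),
                flagged=True,
                note=str(exc),
            )
        records.append(rec)

    for rec in records:
        if rec.flagged:
            continue
        try:
            rec.f1 = float(len(rec.subset))
            rec.f2 = float(evaluator(rec.subset))
        except Exception as exc:  # noqa: BLE001 - evaluator is user code
            logger.warning("evaluator failed for lambda=%g: %s", rec.lam, exc)
            rec.flagged = True
            rec.note = f"evaluator failed: {exc}"

    points = [
        ParetoPoint(objectives=(rec.f1, rec.f2), payload=rec)
        for rec in records
        if not rec.flagged
    ]
    if not points:
        raise RuntimeError("every lambda record was flagged; no Pareto front")
    front = extract_pareto(points)
    return GmofsResult(records=records, pareto_front=front, n_trainings=n_trainings)


# ---------------------------------------------------------------------------
# subset evaluators (Step 4 plumbing)


def make_cv_evaluator(
    table: FeatureTable,
    classifier=None,
    scheme: CvScheme | None = None,
    normalize_scope: str = "train_only",
) -> Callable[[np.ndarray], float]:
    """CV-error callback over masked columns with a library classifier."""
    if classifier is None:
        classifier = make_classifier("lda")
    if scheme is None:
        scheme = CvScheme(kind="random_kfold", folds=10, seed=0)

    def evaluate(subset: np.ndarray) -> float:
        if len(subset) == 0:
            raise ValueError("cannot evaluate an empty subset")
        sub = table.select_columns(np.sort(np.asarray(subset, dtype=int)))
        return crossval_error(sub, classifier, scheme, normalize_scope).mean_error

    return evaluate


def make_mlp_subset_evaluator(
    table: FeatureTable,
    config: GmofsConfig,
    scheme: CvScheme | None = None,
) -> Callable[[np.ndarray], float]:
    """Default Step-4 evaluator: the same constrained-MLP family retrained
    without the penalty (lambda = 0, beta fixed at 1) on the masked columns."""
    if scheme is None:
        scheme = CvScheme(kind="random_kfold", folds=10, seed=0)
    T_all, classes = one_hot_targets(
        table.labels, low=config.target_low, high=config.target_high
    )

    def evaluate(subset: np.ndarray) -> float:
        if len(subset) == 0:
            raise ValueError("cannot evaluate an empty subset")
        cols = np.sort(np.asarray(subset, dtype=int))
        X = table.values[:, cols]
        errors = []
        rng = np.random.default_rng(config.seed)
        for train, test in scheme.split(table.labels):
            mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr, Xte = (X[train] - mu) / sd, (X[test] - mu) / sd
            res = train_constrained(
                Xtr, T_all[train], 0.0, config,
                rng=np.random.default_rng(rng.integers(2**63)),
            )
            pred = np.argmax(forward(res.model, Xte), axis=1)
            truth = np.argmax(T_all[test], axis=1)
            errors.append(float(np.mean(pred != truth)))
        return float(np.mean(errors))

    return evaluate
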