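"""Binary biogeography-based optimization with four multi-objective
selection schemes (VEBBO, NSBBO, NPBBO, SPBBO).

Each individual is a feature mask; objectives (subset size, CV error) are
minimized.  Per generation, each individual immigrates bits from donors
drawn by emigration rate, then mutates; elites by the variant's scalar
fitness pass through unchanged.  An external non-dominated archive over all
evaluated individuals is the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .evaluation import CvScheme, crossval_error, make_classifier
from .features import FeatureTable
from .pareto import ParetoArchive, ParetoPoint, dominates

logger = logging.getLogger(__name__)

__all__ = [
    "BboConfig",
    "Individual",
    "ObjectiveEvaluator",
    "MobboRun",
    "migration_rates",
    "generation_step",
    "run_mobbo",
    "expected_generation_evaluations",
]

VARIANTS = ("vebbo", "nsbbo", "npbbo", "spbbo")

#: Fitness-sharing radius in normalized objective space (NPBBO).
SHARING_RADIUS = 0.1


@dataclass
class BboConfig:
    dimension: int
    mutation_rate: float = 0.04
    elites: int = 2
    pop_size: int = 100
    generations: int = 1000
    migration_model: str = "sinusoidal"
    variant: str = "nsbbo"
    cv_folds: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if not 0 <= self.elites <= self.pop_size:
            raise ValueError("need 0 <= elites <= population size")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.migration_model not in ("sinusoidal", "linear"):
            raise ValueError(f"unknown migration model {self.migration_model!r}")
        if self.variant.lower() not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.variant = self.variant.lower()


@dataclass
class Individual:
    mask: np.ndarray
    objectives: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


class ObjectiveEvaluator:
    """(subset size, c-fold CV error) of a mask, with fold reuse and memoization.

    Folds are fixed once from the seed and shared by every evaluation, so
    dominance comparisons are free of fold noise.  The cache is keyed on the
    mask; ``n_evaluations`` counts logical evaluations (cache hits included)
    while ``n_trainings`` counts actual classifier fits.
    """

    def __init__(
        self,
        table: FeatureTable,
        classifier=None,
        folds: int = 10,
        seed: int | None = None,
        normalize_scope: str = "train_only",
    ) -> None:
        self.table = table
        self.classifier = classifier if classifier is not None else make_classifier("lda")
        self.scheme = CvScheme(kind="random_kfold", folds=folds, seed=seed)
        self.normalize_scope = normalize_scope
        self._cache: dict[bytes, tuple[float, float]] = {}
        self.n_evaluations = 0
        self.n_trainings = 0

    @property
    def dimension(self) -> int:
        return self.table.n_features

    def evaluate(self, individual: Individual) -> tuple[float, float]:
        mask = individual.mask
        if len(mask) != self.dimension:
            raise ValueError(
                f"mask length {len(mask)} != table width {self.dimension}"
            )
        if not mask.any():
            raise ValueError("all-zero mask must be repaired before evaluation")
        self.n_evaluations += 1
        key = mask.tobytes()
        if key not in self._cache:
            cols = np.nonzero(mask)[0]
            sub = self.table.select_columns(cols)
            res = crossval_error(
                sub, self.classifier, self.scheme, self.normalize_scope
            )
            self.n_trainings += len(res.fold_errors)
            self._cache[key] = (float(mask.sum()), res.mean_error)
        individual.objectives = self._cache[key]
        return individual.objectives


def migration_rates(
    rank: int, n: int, model: str = "sinusoidal"
) -> tuple[float, float]:
    """(immigration, emigration) for a 1-based fitness rank (best = 1).

    Sinusoidal rates sum to 1 at every rank; good individuals emigrate,
    poor individuals immigrate.
    """
    if not 1 <= rank <= n:
        raise ValueError("rank must be in 1..N")
    if model == "sinusoidal":
        imm = 0.5 * (math.cos(math.pi * (n - rank) / n) + 1.0)
        emi = 0.5 * (math.cos(math.pi * rank / n) + 1.0)
    elif model == "linear":
        imm = rank / n
        emi = 1.0 - rank / n
    else:
        raise ValueError(f"unknown migration model {model!r}")
    return imm, emi


# ---------------------------------------------------------------------------
# variant scalar fitness


def _normalized_objectives(objs: np.ndarray, dimension: int) -> np.ndarray:
    out = objs.astype(float).copy()
    out[:, 0] /= dimension  # subset size -> [0, 1]; error already a fraction
    return out


def _domination_counts(objs: np.ndarray) -> np.ndarray:
    """For each row, how many other rows strictly dominate it."""
    n = len(objs)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        le = np.all(objs <= objs[i], axis=1)
        lt = np.any(objs < objs[i], axis=1)
        counts[i] = int(np.sum(le & lt))
    return counts


def _nondominated_sort(objs: np.ndarray) -> np.ndarray:
    """Front index (0 = best) per row, by repeated non-dominated peeling."""
    n = len(objs)
    fronts = np.full(n, -1, dtype=int)
    remaining = np.arange(n)
    level = 0
    while len(remaining):
        sub = objs[remaining]
        counts = _domination_counts(sub)
        current = remaining[counts == 0]
        fronts[current] = level
        remaining = remaining[counts != 0]
        level += 1
    return fronts


def _crowding_distance(objs: np.ndarray) -> np.ndarray:
    """Crowding distance within one front (larger = less crowded)."""
    n, m = objs.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(objs[:, j], kind="stable")
        span = objs[order[-1], j] - objs[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span == 0:
            continue
        dist[order[1:-1]] += (objs[order[2:], j] - objs[order[:-2], j]) / span
    return dist


def _niche_counts(norm_objs: np.ndarray, radius: float = SHARING_RADIUS) -> np.ndarray:
    """Triangular fitness-sharing niche count in normalized objective space."""
    diff = norm_objs[:, None, :] - norm_objs[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    share = np.maximum(0.0, 1.0 - d / radius)
    return share.sum(axis=1)


def _spea_fitness(objs: np.ndarray, archive_objs: np.ndarray | None) -> np.ndarray:
    """Strength-Pareto fitness (lower = better) over population plus archive."""
    pool = objs if archive_objs is None or not len(archive_objs) else np.vstack(
        [objs, archive_objs]
    )
    npop = len(objs)
    ntot = len(pool)
    strength = np.zeros(ntot)
    for i in range(ntot):
        le = np.all(pool[i] <= pool, axis=1)
        lt = np.any(pool[i] < pool, axis=1)
        strength[i] = np.sum(le & lt)
    raw = np.zeros(npop)
    for i in range(npop):
        le = np.all(pool <= objs[i], axis=1)
        lt = np.any(pool < objs[i], axis=1)
        raw[i] = strength[le & lt].sum()
    # density: inverse distance to the k-th neighbor in the pool
    k = max(1, int(math.sqrt(ntot)))
    diff = objs[:, None, :] - pool[None, :, :]
    d = np.sort(np.sqrt(np.sum(diff**2, axis=-1)), axis=1)
    kth = d[:, min(k, ntot - 1)]
    return raw + 1.0 / (kth + 2.0)


def _fitness_keys(
    objs: np.ndarray,
    config: BboConfig,
    rng: np.random.Generator,
    archive_objs: np.ndarray | None,
) -> np.ndarray:
    """Per-individual sort keys (lexicographic rows; smaller = fitter)."""
    norm = _normalized_objectives(objs, config.dimension)
    n = len(objs)
    if config.variant == "vebbo":
        # even split across the two objectives, reshuffled every generation
        assignment = np.zeros(n, dtype=int)
        assignment[n // 2 :] = 1
        rng.shuffle(assignment)
        key = norm[np.arange(n), assignment]
        return np.column_stack([key, np.zeros(n)])
    if config.variant == "nsbbo":
        fronts = _nondominated_sort(norm)
        crowd = np.zeros(n)
        for level in np.unique(fronts):
            idx = np.nonzero(fronts == level)[0]
            crowd[idx] = _crowding_distance(norm[idx])
        return np.column_stack([fronts.astype(float), -crowd])
    if config.variant == "npbbo":
        dom = _domination_counts(norm).astype(float)
        niche = _niche_counts(norm)
        return np.column_stack([dom, niche])
    if config.variant == "spbbo":
        fit = _spea_fitness(norm, archive_objs)
        return np.column_stack([fit, np.zeros(n)])
    raise AssertionError(config.variant)


def _rank_population(
    objs: np.ndarray,
    config: BboConfig,
    rng: np.random.Generator,
    archive_objs: np.ndarray | None,
) -> np.ndarray:
    """Indices sorted best-to-worst by the variant's scalar fitness."""
    keys = _fitness_keys(objs, config, rng, archive_objs)
    return np.lexsort((keys[:, 1], keys[:, 0]))


# ---------------------------------------------------------------------------
# archive


class _Archive:
    """External non-dominated store over every evaluated individual."""

    def __init__(self) -> None:
        self._points: dict[bytes, tuple[tuple[float, float], np.ndarray]] = {}

    def add(self, mask: np.ndarray, objectives: tuple[float, float]) -> None:
        obj = np.asarray(objectives, dtype=float)
        for key, (other, _) in list(self._points.items()):
            if dominates(other, obj):
                return
        for key, (other, _) in list(self._points.items()):
            if dominates(obj, other):
                del self._points[key]
        self._points[mask.tobytes()] = (tuple(objectives), mask.copy())

    def objective_array(self) -> np.ndarray:
        if not self._points:
            return np.empty((0, 2))
        return np.array([obj for obj, _ in self._points.values()], dtype=float)

    def to_pareto_archive(self) -> ParetoArchive:
        pts = [
            ParetoPoint(objectives=obj, payload=np.nonzero(mask)[0].tolist())
            for obj, mask in sorted(
                self._points.values(), key=lambda t: t[0]
            )
        ]
        return ParetoArchive(pts)


def _repair_zero_masks(masks: np.ndarray, rng: np.random.Generator) -> None:
    for i in np.nonzero(~masks.any(axis=1))[0]:
        masks[i, rng.integers(masks.shape[1])] = True


def generation_step(
    population: list[Individual],
    config: BboConfig,
    evaluator: ObjectiveEvaluator,
    rng: np.random.Generator,
    archive: "_Archive | None" = None,
) -> list[Individual]:
    """One BBO generation: rank, migrate, mutate, preserve elites, evaluate."""
    n, d = config.pop_size, config.dimension
    objs = np.array([ind.objectives for ind in population], dtype=float)
    archive_objs = archive.objective_array() if archive is not None else None
    order = _rank_population(objs, config, rng, archive_objs)
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)

    rates = np.array(
        [migration_rates(r, n, config.migration_model) for r in ranks]
    )
    imm, emi = rates[:, 0], rates[:, 1]
    emi_p = emi / emi.sum() if emi.sum() > 0 else np.full(n, 1.0 / n)

    masks = np.array([ind.mask for ind in population], dtype=bool)
    new_masks = masks.copy()
    elite_set = set(order[: config.elites].tolist())
    migrate = rng.random((n, d)) < imm[:, None]
    sources = rng.choice(n, size=(n, d), p=emi_p)
    mutate = rng.random((n, d)) < config.mutation_rate
    for i in range(n):
        if i in elite_set:
            continue  # elites pass through untouched
        row = new_masks[i]
        row[migrate[i]] = masks[sources[i], np.arange(d)][migrate[i]]
        row[mutate[i]] = ~row[mutate[i]]
    _repair_zero_masks(new_masks, rng)

    next_pop = [Individual(mask=new_masks[i]) for i in range(n)]
    for i in elite_set:
        next_pop[i].objectives = population[i].objectives
    for ind in next_pop:
        evaluator.evaluate(ind)
        if archive is not None:
            archive.add(ind.mask, ind.objectives)  # type: ignore[arg-type]
    return next_pop


@dataclass
class MobboRun:
    archive: ParetoArchive
    n_generation_evaluations: int
    n_initial_evaluations: int
    n_trainings: int
    final_population: list[Individual] = field(default_factory=list)

    @property
    def n_total_evaluations(self) -> int:
        return self.n_generation_evaluations + self.n_initial_evaluations


def expected_generation_evaluations(pop_size: int, generations: int) -> int:
    """Bookkeeping formula: one objective evaluation per individual per
    generation (the seeded initial population is counted separately)."""
    return pop_size * generations


def run_mobbo(config: BboConfig, evaluator: ObjectiveEvaluator) -> MobboRun:
    """Seeded run of ``generations`` BBO generations; returns the external
    non-dominated archive plus evaluation bookkeeping."""
    if evaluator.dimension != config.dimension:
        raise ValueError("evaluator table width != configured dimension")
    rng = np.random.default_rng(config.seed)
    masks = rng.random((config.pop_size, config.dimension)) < 0.5
    _repair_zero_masks(masks, rng)
    archive = _Archive()
    start_evals = evaluator.n_evaluations
    population = [Individual(mask=m) for m in masks]
    for ind in population:
        evaluator.evaluate(ind)
        archive.add(ind.mask, ind.objectives)  # type: ignore[arg-type]
    n_initial = evaluator.n_evaluations - start_evals

    gen_start = evaluator.n_evaluations
    for _ in range(config.generations):
        population = generation_step(population, config, evaluator, rng, archive)
    n_generation = evaluator.n_evaluations - gen_start
    assert n_generation == expected_generation_evaluations(
        config.pop_size, config.generations
    )
    return MobboRun(
        archive=archive.to_pareto_archive(),
        n_generation_evaluations=n_generation,
        n_initial_evaluations=n_initial,
        n_trainings=evaluator.n_trainings,
        final_population=population,
    )
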