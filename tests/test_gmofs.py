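import numpy as np
import pytest
from scipy.stats import spearmanr

from gaitsel import gmofs, synth
from gaitsel.evaluation import CvScheme
from gaitsel.features import normalize_table
from gaitsel.gmofs import (
    GmofsConfig,
    GmofsModel,
    cost,
    default_lambda_grid,
    forward,
    gradients,
    initialize_model,
    make_cv_evaluator,
    one_hot_targets,
    parse_lambda_grid,
    run_gmofs,
    select_significant,
    train_constrained,
)
from gaitsel.pareto import dominates


def random_model(rng, n, p, k, beta_range=(0.1, 0.9)):
    return GmofsModel(
        beta=rng.uniform(*beta_range, size=n),
        V=rng.uniform(-1, 1, size=(n + 1, p - 1)),
        W=rng.uniform(-1, 1, size=(p, k)),
    )


def pack(model):
    return np.concatenate([model.beta, model.V.ravel(), model.W.ravel()])


def unpack(theta, n, p, k):
    nv = (n + 1) * (p - 1)
    return GmofsModel(
        beta=theta[:n],
        V=theta[n : n + nv].reshape(n + 1, p - 1),
        W=theta[n + nv :].reshape(p, k),
    )


class TestLambdaGrid:
    def test_default_grid_has_43_values(self):
        grid = default_lambda_grid()
        assert len(grid) == 43
        assert grid[0] == 0.0
        assert grid[-1] == 150.0
        assert np.all(np.diff(grid[:31]) == 1.0)
        assert np.all(np.diff(grid[31:]) == 10.0)

    def test_parse_matches_default(self):
        np.testing.assert_array_equal(
            parse_lambda_grid("0:1:30,40:10:150"), default_lambda_grid()
        )

    def test_parse_rejects_negative(self):
        with pytest.raises(ValueError):
            parse_lambda_grid("-5:1:5")

    def test_parse_rejects_decreasing(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            parse_lambda_grid("10:1:20,0:1:5")


class TestForward:
    def test_zero_beta_blocks_inputs(self, rng):
        model = random_model(rng, 4, 3, 2, beta_range=(0.0, 0.0))
        o1 = forward(model, rng.normal(size=4))
        o2 = forward(model, rng.normal(size=4) * 100)
        np.testing.assert_allclose(o1, o2)

    def test_hand_computed_tiny_network(self):
        # 2 inputs, p=2 (1 free hidden + bias), 1 output
        model = GmofsModel(
            beta=np.array([1.0, 1.0]),
            V=np.array([[0.5], [-0.25], [0.1]]),  # w for x1, x2, input bias
            W=np.array([[0.3], [-0.2]]),  # free hidden, hidden bias
        )
        x = np.array([1.0, 2.0])
        h = 1.0 / (1.0 + np.exp(-(0.5 * 1.0 - 0.25 * 2.0 + 0.1)))
        expected = 1.0 / (1.0 + np.exp(-(0.3 * h - 0.2)))
        assert forward(model, x)[0] == pytest.approx(expected, rel=1e-12)

    def test_beta_input_scaling_equivalence(self, rng):
        model = random_model(rng, 3, 4, 2)
        x = rng.normal(size=3)
        c = 2.5
        scaled = GmofsModel(
            beta=model.beta / c, V=model.V.copy(), W=model.W.copy()
        )
        np.testing.assert_allclose(
            forward(model, x), forward(scaled, c * x), rtol=1e-12
        )

    def test_outputs_in_unit_interval(self, rng):
        model = random_model(rng, 5, 3, 4)
        O = forward(model, rng.normal(size=(20, 5)))
        assert O.shape == (20, 4)
        assert np.all((O > 0) & (O < 1))

    def test_dimension_mismatch(self, rng):
        model = random_model(rng, 5, 3, 2)
        with pytest.raises(ValueError, match="inputs"):
            forward(model, np.zeros(7))


class TestCost:
    def test_lambda_zero_is_pure_error(self, rng):
        model = random_model(rng, 3, 3, 2)
        X = rng.normal(size=(10, 3))
        T = rng.uniform(0, 1, size=(10, 2))
        O = forward(model, X)
        assert cost(model, X, T, 0.0, 0.5) == pytest.approx(
            0.5 * np.sum((T - O) ** 2)
        )

    def test_penalty_hand_arithmetic(self, rng):
        # perfect outputs are unreachable with sigmoids, so isolate the
        # penalty as J(lam) - J(0)
        model = random_model(rng, 1, 2, 1)
        model.beta = np.array([0.5])
        X = rng.normal(size=(4, 1))
        T = rng.uniform(size=(4, 1))
        penalty = cost(model, X, T, 2.0, 0.5) - cost(model, X, T, 0.0, 0.5)
        assert penalty == pytest.approx(2.0 * (0.5 * 0.25 + 0.5 * 0.5))
        assert penalty == pytest.approx(0.75)

    def test_pure_l1_at_alpha_zero(self, rng):
        model = random_model(rng, 6, 3, 2)
        X = rng.normal(size=(5, 6))
        T = rng.uniform(size=(5, 2))
        penalty = cost(model, X, T, 3.0, 0.0) - cost(model, X, T, 0.0, 0.0)
        assert penalty == pytest.approx(3.0 * np.sum(np.abs(model.beta)))

    def test_cost_nonnegative(self, rng):
        for _ in range(5):
            model = random_model(rng, 4, 3, 3)
            X = rng.normal(size=(8, 4))
            T = rng.uniform(size=(8, 3))
            assert cost(model, X, T, rng.uniform(0, 10), rng.uniform(0, 1)) >= 0


class TestGradients:
    def test_finite_difference_agreement_20_instances(self):
        """Analytic gradients vs central differences (independent oracle)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            p = int(rng.integers(2, 5))
            k = int(rng.integers(1, 4))
            m = 8
            model = random_model(rng, n, p, k)
            X = rng.normal(size=(m, n))
            T = rng.uniform(0.05, 0.95, size=(m, k))
            lam = float(rng.uniform(0, 5))
            alpha = float(rng.uniform(0, 1))
            db, dV, dW = gradients(model, X, T, lam, alpha)
            g = np.concatenate([db, dV.ravel(), dW.ravel()])
            theta0 = pack(model)
            h = 1e-5
            fd = np.empty_like(theta0)
            for i in range(len(theta0)):
                tp, tm = theta0.copy(), theta0.copy()
                tp[i] += h
                tm[i] -= h
                fd[i] = (
                    cost(unpack(tp, n, p, k), X, T, lam, alpha)
                    - cost(unpack(tm, n, p, k), X, T, lam, alpha)
                ) / (2 * h)
            rel = np.linalg.norm(g - fd) / np.linalg.norm(fd)
            assert rel <= 1e-6

    def test_l1_penalty_gradient_is_lambda(self, rng):
        model = random_model(rng, 3, 3, 2)
        X = rng.normal(size=(6, 3))
        T = rng.uniform(size=(6, 2))
        lam = 4.0
        db0, _, _ = gradients(model, X, T, 0.0, 0.0)
        db1, _, _ = gradients(model, X, T, lam, 0.0)
        np.testing.assert_allclose(db1 - db0, lam * np.ones(3), rtol=1e-12)

    def test_l1_subgradient_zero_at_zero(self, rng):
        model = random_model(rng, 3, 3, 2, beta_range=(0.0, 0.0))
        X = rng.normal(size=(6, 3))
        T = rng.uniform(size=(6, 2))
        db0, _, _ = gradients(model, X, T, 0.0, 0.0)
        db1, _, _ = gradients(model, X, T, 5.0, 0.0)
        np.testing.assert_allclose(db1, db0)

    def test_near_perfect_fit_small_gradients(self, rng):
        model = random_model(rng, 2, 3, 2)
        X = rng.normal(size=(5, 2))
        T = forward(model, X)  # targets equal outputs exactly
        db, dV, dW = gradients(model, X, T, 0.0, 0.0)
        assert np.allclose(db, 0) and np.allclose(dV, 0) and np.allclose(dW, 0)


class TestTrainConstrained:
    def test_bounds_hold_and_cost_decreases(self, rng):
        cfg = GmofsConfig(hidden_nodes=4, lambda_grid=[1.0], seed=0)
        for trial in range(3):
            X = rng.normal(size=(30, 5))
            T, _ = one_hot_targets(rng.integers(0, 2, size=30))
            res = train_constrained(X, T, 1.0, cfg,
                                    rng=np.random.default_rng(trial))
            assert res.model.check_bounds(cfg.weight_bound_a, cfg.weight_bound_b)
            assert res.final_cost <= res.initial_cost

    def test_planted_informative_feature_wins(self):
        """Exhaustive single-feature errors confirm column 0 is informative;
        training should give it the largest multiplier in >= 9/10 runs."""
        table = synth.generate_planted_table(
            synth.PlantedTableConfig(
                m=100, n=5, informative=(0,), effect_size=4.0, seed=6
            )
        )
        norm = normalize_table(table)
        # independent check: single-feature LDA errors
        from gaitsel.evaluation import CvScheme, crossval_error, make_classifier

        errs = [
            crossval_error(
                norm.select_columns([j]), make_classifier("lda"),
                CvScheme(folds=5, seed=0),
            ).mean_error
            for j in range(5)
        ]
        assert np.argmin(errs) == 0

        T, _ = one_hot_targets(norm.labels)
        cfg = GmofsConfig(hidden_nodes=4, lambda_grid=[3.0], alpha=0.0)
        wins = 0
        for seed in range(10):
            res = train_constrained(
                norm.values, T, 3.0, cfg, rng=np.random.default_rng(seed)
            )
            wins += int(np.argmax(res.model.beta) == 0)
        assert wins >= 9


class TestSelectSignificant:
    def test_dominant_feature_still_needs_second(self):
        subset = select_significant(np.array([0.9, 0.05, 0.05]), 0.95)
        assert len(subset) == 2
        assert subset[0] == 0

    def test_equal_betas_need_all_ten(self):
        subset = select_significant(np.full(10, 0.3), 0.95)
        assert len(subset) == 10

    def test_single_feature(self):
        assert list(select_significant(np.array([0.2]), 0.95)) == [0]

    def test_ties_broken_by_lower_index(self):
        subset = select_significant(np.array([0.4, 0.6, 0.4]), 0.70)
        assert list(subset) == [1, 0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            select_significant(np.zeros(4))

    def test_threshold_one_returns_support(self):
        subset = select_significant(np.array([0.5, 0.0, 0.5]), 1.0)
        assert sorted(subset) == [0, 2]


@pytest.fixture(scope="module")
def sweep():
    """Full default-grid sweep on the planted table (shared across tests)."""
    table = synth.generate_planted_table(
        synth.PlantedTableConfig(
            m=240, n=30, informative=(0, 1, 2, 3, 4), effect_size=1.2, seed=42
        )
    )
    norm = normalize_table(table)
    T, _ = one_hot_targets(norm.labels)
    cfg = GmofsConfig(seed=7)
    evaluator = make_cv_evaluator(norm, scheme=CvScheme(folds=5, seed=3))
    return run_gmofs(norm.values, T, cfg, evaluator)


class TestRunGmofs:
    def test_43_trainings_on_default_grid(self, sweep):
        assert sweep.n_trainings == 43

    def test_pareto_front_mutually_nondominated(self, sweep):
        objs = [p.objectives for p in sweep.pareto_front.points]
        for i, a in enumerate(objs):
            for j, b in enumerate(objs):
                if i != j:
                    assert not dominates(a, b)

    def test_pareto_matches_brute_force_oracle(self, sweep):
        candidates = [
            (r.f1, r.f2, r.lam) for r in sweep.records if not r.flagged
        ]
        brute = [
            (f1, f2, lam)
            for f1, f2, lam in candidates
            if not any(
                dominates((g1, g2), (f1, f2))
                for g1, g2, _ in candidates
            )
        ]
        front = [
            (p.objectives[0], p.objectives[1], p.payload.lam)
            for p in sweep.pareto_front.points
        ]
        assert sorted(front) == sorted(brute)

    def test_subset_size_shrinks_with_lambda(self, sweep):
        ok = [r for r in sweep.records if not r.flagged]
        largest_lam = max(ok, key=lambda r: r.lam)
        at_zero = next(r for r in ok if r.lam == 0.0)
        assert len(largest_lam.subset) <= len(at_zero.subset)

    def test_spearman_lambda_vs_size_negative(self, sweep):
        lams = [r.lam for r in sweep.records]
        sizes = [len(r.subset) for r in sweep.records]
        rho, _ = spearmanr(lams, sizes)
        assert rho < 0

    def test_every_pareto_point_references_a_record(self, sweep):
        for p in sweep.pareto_front.points:
            assert p.payload in sweep.records

    def test_planted_recovery_with_few_extras(self, sweep):
        planted = {0, 1, 2, 3, 4}
        hits = [
            p
            for p in sweep.pareto_front.points
            if planted <= set(p.payload.subset.tolist())
        ]
        assert hits, "no Pareto subset contains all planted features"
        assert min(
            len(set(p.payload.subset.tolist()) - planted) for p in hits
        ) <= 2

    def test_large_subsets_mostly_planted(self, sweep):
        planted = {0, 1, 2, 3, 4}
        for p in sweep.pareto_front.points:
            subset = set(p.payload.subset.tolist())
            if len(subset) >= 5:
                assert len(subset & planted) >= 4


class TestInitialization:
    def test_seeded_ranges(self, rng):
        cfg = GmofsConfig(hidden_nodes=4, lambda_grid=[0.0])
        model = initialize_model(6, 4, 3, cfg, rng)
        assert np.all((model.beta >= 0.4) & (model.beta <= 0.6))
        assert np.all(np.abs(model.V) <= 0.1 * cfg.weight_bound_b)
        assert np.all(np.abs(model.W) <= 0.1 * cfg.weight_bound_a)
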