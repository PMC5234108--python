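import json

import numpy as np
import pytest

from stentopt import (
    ConvergenceCriteria,
    IterationRecord,
    OptimizationRun,
    Prediction,
    SampleDesign,
    TrainingSet,
    check_convergence,
    expected_improvement,
    fit,
    make_space,
    maximize_ei,
    predict,
    run,
)
from stentopt.ego_optimizer import EvaluatorError
from stentopt.kriging import fit_fixed_theta


def training_1d(x, y):
    sp = make_space([("x", 0.0, 1.0)])
    return TrainingSet(SampleDesign(sp, np.asarray(x, float)[:, None]), y)


class TestExpectedImprovement:
    def test_no_uncertainty_no_improvement(self):
        assert expected_improvement(1.0, Prediction(mean=2.0, variance=0.0)) == 0.0

    def test_no_uncertainty_deterministic_improvement(self):
        assert expected_improvement(1.0, Prediction(mean=-1.0, variance=0.0)) == 2.0

    def test_standard_normal_value(self):
        # E[max(-Y, 0)] for Y ~ N(0,1) is phi(0) = 1/sqrt(2*pi)
        ei = expected_improvement(0.0, Prediction(mean=0.0, variance=1.0))
        assert ei == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(123)
        draws = rng.normal(size=1_000_000)
        for f_min, mean, std in [(0.0, 0.0, 1.0), (0.5, 0.2, 0.7), (-1.0, 0.0, 2.0)]:
            mc = np.mean(np.maximum(f_min - (mean + std * draws), 0.0))
            ei = expected_improvement(f_min, Prediction(mean=mean, variance=std**2))
            assert ei == pytest.approx(mc, abs=2e-3)

    def test_nonnegative_everywhere(self):
        for mean in (-5.0, 0.0, 5.0):
            for var in (0.0, 0.3, 4.0):
                assert expected_improvement(0.0, Prediction(mean, var)) >= 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(np.nan, Prediction(0.0, 1.0))
        with pytest.raises(ValueError):
            expected_improvement(0.0, Prediction(np.inf, 1.0))


class TestMaximizeEI:
    def test_constant_data_peak_at_max_variance(self):
        """With a flat response the EI landscape is driven purely by the
        predictive spread; verified against a dense grid scan."""
        ts = training_1d([0.0, 0.5, 1.0], np.zeros(3))
        model = fit_fixed_theta(ts, 30.0)
        sp = ts.design.space
        x_best, ei_best = maximize_ei(model, 0.0, sp, seed=0)
        grid = np.linspace(0, 1, 10_001)
        ei_grid = max(
            expected_improvement(0.0, predict(model, [g])) for g in grid
        )
        assert ei_best >= ei_grid - 1e-9

    def test_v_shape_matches_grid_scan(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = np.abs(x - 0.4)
        model = fit(training_1d(x, y), seed=0)
        sp = model.space
        _, ei_best = maximize_ei(model, y.min(), sp, seed=1)
        grid = np.linspace(0, 1, 10_001)
        ei_grid = max(
            expected_improvement(y.min(), predict(model, [g])) for g in grid
        )
        assert ei_best >= ei_grid - 1e-9


class TestCheckConvergence:
    def _training(self):
        return training_1d([0.0, 0.5, 1.0], np.array([0.0, 2.0, 1.0]))

    def test_all_conditions_met(self):
        rec = IterationRecord(1, np.array([0.1]), 0.0, 1.0, 1.0, (False,) * 3)
        ok, flags = check_convergence(
            rec, previous_f=1.0, training=self._training(),
            criteria=ConvergenceCriteria(),
        )
        assert ok and flags == (True, True, True)

    def test_ei_ratio_violation(self):
        crit = ConvergenceCriteria(eps1=0.01)
        rec = IterationRecord(1, np.array([0.1]), 0.04, 1.0, 1.0, (False,) * 3)
        ok, flags = check_convergence(rec, 1.0, self._training(), crit)
        assert not ok and flags == (False, True, True)

    def test_surrogate_error_violation(self):
        crit = ConvergenceCriteria(eps1=0.01, eps2=0.1)
        rec = IterationRecord(1, np.array([0.1]), 0.001, 0.5, 1.0, (False,) * 3)
        ok, flags = check_convergence(rec, 1.0, self._training(), crit)
        assert not ok and flags[0] and not flags[1]

    def test_degenerate_range_treats_ei_ratio_as_zero(self):
        ts = training_1d([0.0, 0.5, 1.0], np.full(3, 2.0))
        rec = IterationRecord(1, np.array([0.1]), 5.0, 2.0, 2.0, (False,) * 3)
        ok, flags = check_convergence(rec, 2.0, ts, ConvergenceCriteria())
        assert flags[0]


class TestRun:
    def test_quadratic_recovery(self):
        sp = make_space([("x", 0.0, 1.0)])
        result = run(lambda x: (x[0] - 0.3) ** 2, sp, n_init=5, seed=1)
        assert abs(result.best_point[0] - 0.3) <= 0.01
        assert result.best_value <= 1e-3

    def test_every_evaluation_inside_bounds(self):
        sp = make_space([("x", -2.0, 4.0)])
        result = run(lambda x: np.sin(x[0]) + 0.1 * x[0] ** 2, sp, n_init=6,
                     seed=3)
        for it in result.iterations:
            assert sp.contains(it.point)

    def test_running_best_non_increasing(self):
        sp = make_space([("x", 0.0, 1.0)])
        result = run(lambda x: (x[0] - 0.62) ** 2, sp, n_init=5, seed=2)
        best = min(result.initial_responses)
        for it in result.iterations:
            assert min(best, it.evaluated) <= best + 1e-15
            best = min(best, it.evaluated)
        assert result.best_value == pytest.approx(best)

    def test_infinite_tolerances_stop_after_one_iteration(self):
        sp = make_space([("x", 0.0, 1.0)])
        crit = ConvergenceCriteria(eps1=np.inf, eps2=np.inf, eps3=np.inf,
                                   max_iterations=50)
        result = run(lambda x: x[0] ** 2, sp, n_init=5, criteria=crit, seed=0)
        assert result.status == "converged"
        assert len(result.iterations) == 1

    def test_zero_budget_returns_best_initial_sample(self):
        sp = make_space([("x", 0.0, 1.0)])
        crit = ConvergenceCriteria(max_iterations=0)
        result = run(lambda x: (x[0] - 0.3) ** 2, sp, n_init=5, criteria=crit,
                     seed=0)
        assert result.status == "budget_exhausted"
        assert len(result.iterations) == 0
        assert result.best_value == min(result.initial_responses)

    def test_seeded_determinism_bit_exact_json(self):
        sp = make_space([("x", 0.0, 1.0)])
        crit = ConvergenceCriteria(max_iterations=3)
        r1 = run(lambda x: np.cos(5 * x[0]), sp, n_init=4, criteria=crit, seed=9)
        r2 = run(lambda x: np.cos(5 * x[0]), sp, n_init=4, criteria=crit, seed=9)
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())

    def test_maximization_sense(self):
        sp = make_space([("x", 0.0, 1.0)])
        result = run(lambda x: -((x[0] - 0.7) ** 2), sp, n_init=5, seed=4,
                     sense="max")
        assert abs(result.best_point[0] - 0.7) <= 0.02
        assert result.best_value == pytest.approx(0.0, abs=1e-3)

    def test_evaluator_failure_preserves_partial_history(self, tmp_path):
        sp = make_space([("x", 0.0, 1.0)])
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] > 5:  # the first adaptive evaluation fails
                raise RuntimeError("solver diverged")
            return (x[0] - 0.4) ** 2

        out = tmp_path / "partial.json"
        with pytest.raises(EvaluatorError):
            run(flaky, sp, n_init=5, seed=0, history_path=out)
        saved = OptimizationRun.from_json(out)
        assert saved.n_evaluations >= 5

    def test_run_json_round_trip(self, tmp_path):
        sp = make_space([("x", 0.0, 1.0)])
        crit = ConvergenceCriteria(max_iterations=2)
        result = run(lambda x: (x[0] - 0.5) ** 2, sp, n_init=4, criteria=crit,
                     seed=6)
        path = tmp_path / "run.json"
        result.to_json(path)
        back = OptimizationRun.from_json(path)
        assert back.best_value == result.best_value
        np.testing.assert_array_equal(back.best_point, result.best_point)
        assert back.status == result.status
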