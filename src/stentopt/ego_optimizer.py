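"""Adaptive surrogate optimization loop (efficient global optimization).

One cycle: evaluate the initial space-filling design, fit the Kriging
surrogate, find the point maximising Expected Improvement (EI), evaluate the
black box there, append it to the training set, refit, and repeat.  The loop
stops when three conditions hold simultaneously at an iteration k:

    EI_k / (Y_max - Y_min) <= eps1        (the acquisition has collapsed)
    |f_k - yhat_k|         <= eps2        (the surrogate is locally accurate)
    |f_k - f_{k-1}|        <= eps3        (the objective has stopped moving)

where Y_max, Y_min are the extreme responses among the training samples,
f_k the evaluated objective and yhat_k the surrogate's prediction at the
new point.  The iteration sequence starts from the best initial sample, so
f_0 is the minimum response of the initial design.

Everything is phrased as minimisation; maximisation problems are negated
before entering the loop.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from . import kriging
from .design_space import DesignSpace, SampleDesign, mrg_design
from .kriging import KrigingModel, Prediction, TrainingSet

__all__ = [
    "ConvergenceCriteria",
    "IterationRecord",
    "OptimizationRun",
    "expected_improvement",
    "maximize_ei",
    "check_convergence",
    "run",
    "EvaluatorError",
]

_N_MULTISTART = 64
_N_SCAN = 1024


@dataclass(frozen=True)
class ConvergenceCriteria:
    """Tolerances of the triple stopping test.

    eps1 is dimensionless (EI normalised by the training-response range);
    eps2 and eps3 carry the objective's units.
    """

    eps1: float = 1e-3
    eps2: float = 1e-3
    eps3: float = 1e-3
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not (self.eps1 > 0 and self.eps2 > 0 and self.eps3 > 0):
            raise ValueError("all tolerances must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


@dataclass(frozen=True)
class IterationRecord:
    index: int
    point: np.ndarray
    ei_value: float
    predicted: float
    evaluated: float
    converged_flags: tuple[bool, bool, bool]

    def to_dict(self) -> dict:
        return {
            "k": self.index,
            "point": np.asarray(self.point, float).tolist(),
            "ei": self.ei_value,
            "predicted": self.predicted,
            "evaluated": self.evaluated,
            "converged_flags": list(self.converged_flags),
        }


@dataclass
class OptimizationRun:
    space: DesignSpace
    initial_points: np.ndarray
    initial_responses: np.ndarray
    iterations: list[IterationRecord]
    best_point: np.ndarray
    best_value: float
    status: str  # "converged" | "budget_exhausted"
    sense: str = "min"  # user-facing sense of the objective

    @property
    def n_evaluations(self) -> int:
        return len(self.initial_responses) + len(self.iterations)

    def to_dict(self) -> dict:
        return {
            "variables": [list(v) for v in self.space.variables],
            "sense": self.sense,
            "initial_points": self.initial_points.tolist(),
            "initial_responses": self.initial_responses.tolist(),
            "iterations": [it.to_dict() for it in self.iterations],
            "best_point": np.asarray(self.best_point, float).tolist(),
            "best_value": self.best_value,
            "status": self.status,
        }

    def to_json(self, path) -> None:
        _atomic_write_json(path, self.to_dict())

    @classmethod
    def from_dict(cls, payload: dict) -> "OptimizationRun":
        from .design_space import make_space

        space = make_space(payload["variables"])
        its = [
            IterationRecord(
                index=d["k"],
                point=np.asarray(d["point"], float),
                ei_value=d["ei"],
                predicted=d["predicted"],
                evaluated=d["evaluated"],
                converged_flags=tuple(bool(b) for b in d["converged_flags"]),
            )
            for d in payload["iterations"]
        ]
        return cls(
            space=space,
            initial_points=np.asarray(payload["initial_points"], float),
            initial_responses=np.asarray(payload["initial_responses"], float),
            iterations=its,
            best_point=np.asarray(payload["best_point"], float),
            best_value=float(payload["best_value"]),
            status=payload["status"],
            sense=payload.get("sense", "min"),
        )

    @classmethod
    def from_json(cls, path) -> "OptimizationRun":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class EvaluatorError(RuntimeError):
    """Black-box evaluation failed; carries the partial run history."""

    def __init__(self, message: str, partial: OptimizationRun | None = None):
        super().__init__(message)
        self.partial = partial


def _atomic_write_json(path, payload: dict) -> None:
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=1)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def expected_improvement(f_min: float, prediction: Prediction) -> float:
    """E[max(f_min - Y, 0)] under the surrogate's normal predictive law.

    Degenerates to max(f_min - mean, 0) at zero predictive spread.
    """
    mean, var = prediction.mean, prediction.variance
    if not (np.isfinite(f_min) and np.isfinite(mean) and np.isfinite(var)):
        raise ValueError("non-finite inputs to expected improvement")
    if var < 0:
        raise ValueError("negative predictive variance")
    std = math.sqrt(var)
    if std == 0.0:
        return max(f_min - mean, 0.0)
    u = (f_min - mean) / std
    return max((f_min - mean) * norm.cdf(u) + std * norm.pdf(u), 0.0)


def maximize_ei(
    model: KrigingModel,
    f_min: float,
    space: DesignSpace,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Locate the EI maximiser over the space.

    A seeded space-filling scan picks promising regions; the best scan point
    and a batch of seeded multistarts are then refined with a bounded local
    optimiser.  The returned EI is never below the best candidate seen.
    """
    rng = np.random.default_rng(seed)
    lo, hi = space.lower, space.upper
    d = space.dimension

    def neg_ei(x: np.ndarray) -> float:
        return -expected_improvement(f_min, kriging.predict(model, x))

    scan = rng.uniform(lo, hi, size=(_N_SCAN, d))
    scan_vals = np.array([neg_ei(x) for x in scan])
    order = np.argsort(scan_vals)

    starts = [scan[i] for i in order[:8]]
    starts += [rng.uniform(lo, hi, size=d) for _ in range(_N_MULTISTART - len(starts))]

    best_x = scan[order[0]]
    best_v = scan_vals[order[0]]
    span = hi - lo
    if np.all(span < 1e-12):
        return lo.copy(), -neg_ei(lo)
    bounds = list(zip(lo, hi))
    for s in starts:
        res = optimize.minimize(neg_ei, s, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_v:
            best_v = res.fun
            best_x = np.clip(res.x, lo, hi)
    return np.asarray(best_x, float), float(-best_v)


def check_convergence(
    record: IterationRecord,
    previous_f: float,
    training: TrainingSet,
    criteria: ConvergenceCriteria,
) -> tuple[bool, tuple[bool, bool, bool]]:
    """Evaluate the three stopping inequalities for one iteration."""
    y_range = training.y_max - training.y_min
    ei_ratio = record.ei_value / y_range if y_range > 0 else 0.0
    flags = (
        ei_ratio <= criteria.eps1,
        abs(record.evaluated - record.predicted) <= criteria.eps2,
        abs(record.evaluated - previous_f) <= criteria.eps3,
    )
    return all(flags), flags


def run(
    evaluator,
    space: DesignSpace,
    n_init: int,
    criteria: ConvergenceCriteria | None = None,
    seed: int = 0,
    sense: str = "min",
    shrink: float = 0.1,
    history_path=None,
) -> OptimizationRun:
    """Full adaptive loop: initial MRG design, then EI-driven refinement.

    ``sense`` may be "min" or "max"; maximisation negates the evaluator
    internally and reports results on the user's scale.  Each iteration adds
    exactly one evaluation.  If ``history_path`` is given, the (partial) run
    is flushed to JSON after every iteration; on an evaluator exception an
    :class:`EvaluatorError` carrying the partial history is raised.
    """
    if criteria is None:
        criteria = ConvergenceCriteria()
    if sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")
    sign = 1.0 if sense == "min" else -1.0

    design = mrg_design(space, n_init, shrink=shrink, seed=seed)
    rng = np.random.default_rng(seed)

    def call(x, partial):
        try:
            return sign * float(evaluator(np.asarray(x, float)))
        except Exception as exc:  # noqa: BLE001 - black box may raise anything
            if partial is not None and history_path is not None:
                partial.to_json(history_path)
            raise EvaluatorError(f"evaluator failed at {np.asarray(x).tolist()}: {exc}",
                                 partial) from exc

    responses = np.array([call(x, None) for x in design.points])

    eval_points: list[np.ndarray] = []   # adaptive evaluations, internal scale
    eval_values: list[float] = []

    def snapshot(iters, status) -> OptimizationRun:
        all_y = np.concatenate([responses, eval_values]) if eval_values else responses
        all_x = np.vstack([design.points] + [p[None, :] for p in eval_points]) \
            if eval_points else design.points
        b = int(np.argmin(all_y))
        return OptimizationRun(
            space=space,
            initial_points=design.points,
            initial_responses=sign * responses,
            iterations=list(iters),
            best_point=all_x[b],
            best_value=sign * float(all_y[b]),
            status=status,
            sense=sense,
        )

    points = design.points.copy()
    y = responses.copy()
    iterations: list[IterationRecord] = []
    previous_f = float(np.min(y))  # loop starts from the best initial sample
    status = "budget_exhausted"

    for k in range(1, criteria.max_iterations + 1):
        training = TrainingSet(
            design=SampleDesign(space=space, points=points, scheme="explicit"),
            responses=y,
        )
        model = kriging.fit(training, seed=int(rng.integers(2**31)))
        f_min = float(np.min(y))
        new_x, ei_val = maximize_ei(model, f_min, space,
                                    seed=int(rng.integers(2**31)))
        predicted = kriging.predict(model, new_x).mean
        partial = snapshot(iterations, "budget_exhausted")
        f_new = call(new_x, partial)
        eval_points.append(new_x)
        eval_values.append(f_new)

        done, flags = check_convergence(
            IterationRecord(k, new_x, ei_val, predicted, f_new, (False,) * 3),
            previous_f,
            training,
            criteria,
        )
        record = IterationRecord(k, new_x, ei_val, sign * predicted,
                                 sign * f_new, flags)
        iterations.append(record)

        # duplicate evaluation points would make the correlation matrix
        # singular; keep the first occurrence
        if not any(np.allclose(new_x, p, atol=1e-12) for p in points):
            points = np.vstack([points, new_x])
            y = np.append(y, f_new)
        previous_f = f_new

        if history_path is not None:
            snapshot(iterations, "running").to_json(history_path)
        if done:
            status = "converged"
            break

    result = snapshot(iterations, status)
    if history_path is not None:
        result.to_json(history_path)
    return result
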