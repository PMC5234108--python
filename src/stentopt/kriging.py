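"""Ordinary Kriging: interpolating Gaussian-process surrogate.

The surrogate assumes the response is a realisation of a stationary Gaussian
process with constant (unknown) mean and anisotropic squared-exponential
correlation

    R(x, x') = exp( -sum_l theta_l (x_l - x'_l)^2 )

on coordinates scaled to the unit cube.  Given responses y at training
points, the best linear unbiased predictor at a new point x is

    yhat(x) = mu + r(x)^T R^-1 (y - mu 1),      mu = (1^T R^-1 y)/(1^T R^-1 1)

with predictive variance

    s2(x) = sigma2 [ 1 - r^T R^-1 r + (1 - 1^T R^-1 r)^2 / (1^T R^-1 1) ],

where sigma2 is the process-variance MLE.  Correlation hyperparameters
theta are estimated by maximising the concentrated log-likelihood

    -(n/2) ln sigma2(theta) - (1/2) ln det R(theta)

with seeded multistart local optimisation over log theta.  A small relative
nugget keeps the correlation matrix factorisable; it is escalated tenfold
on failure up to a hard cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .design_space import DesignSpace, SampleDesign

__all__ = ["TrainingSet", "KrigingModel", "Prediction", "fit", "predict"]

_NUGGET = 1e-10
_NUGGET_CAP = 1e-6
# Floor on the process variance so that predictive uncertainty (and the EI
# acquisition built on it) stays defined even for constant responses.
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainingSet:
    design: SampleDesign
    responses: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.responses, dtype=float).ravel()
        object.__setattr__(self, "responses", y)
        if len(y) != len(self.design):
            raise ValueError(
                f"{len(y)} responses for {len(self.design)} design points"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")

    @property
    def y_max(self) -> float:
        return float(np.max(self.responses))

    @property
    def y_min(self) -> float:
        return float(np.min(self.responses))


@dataclass(frozen=True)
class Prediction:
    mean: float
    variance: float
    extrapolating: bool = False

    @property
    def std(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class KrigingModel:
    training: TrainingSet
    theta: np.ndarray          # per-dimension, on unit-cube coordinates
    process_mean: float
    process_variance: float
    nugget: float
    # cached factorisation pieces
    _chol: np.ndarray
    _alpha: np.ndarray         # R^-1 (y - mu 1)
    _rinv_one: np.ndarray      # R^-1 1
    _one_rinv_one: float
    _x_unit: np.ndarray

    @property
    def space(self) -> DesignSpace:
        return self.training.design.space

    def summary(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "process_mean": self.process_mean,
            "process_variance": self.process_variance,
            "nugget": self.nugget,
            "n_training": len(self.training.design),
        }


def _corr_matrix(x_unit: np.ndarray, theta: np.ndarray, nugget: float) -> np.ndarray:
    diff2 = (x_unit[:, None, :] - x_unit[None, :, :]) ** 2
    r = np.exp(-diff2 @ theta)
    r[np.diag_indices_from(r)] += nugget
    return r


def _corr_vector(x_unit: np.ndarray, point_unit: np.ndarray, theta: np.ndarray) -> np.ndarray:
    diff2 = (x_unit - point_unit[None, :]) ** 2
    return np.exp(-diff2 @ theta)


def _neg_concentrated_loglik(log_theta, x_unit, y, nugget):
    theta = np.exp(log_theta)
    n = len(y)
    r = _corr_matrix(x_unit, theta, nugget)
    try:
        chol = linalg.cholesky(r, lower=True)
    except linalg.LinAlgError:
        return 1e30
    one = np.ones(n)
    rinv_y = linalg.cho_solve((chol, True), y)
    rinv_one = linalg.cho_solve((chol, True), one)
    mu = float(one @ rinv_y) / float(one @ rinv_one)
    resid = y - mu
    sigma2 = float(resid @ linalg.cho_solve((chol, True), resid)) / n
    sigma2 = max(sigma2, _VAR_FLOOR)
    log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return 0.5 * (n * np.log(sigma2) + log_det)


def fit(
    training: TrainingSet,
    theta_bounds: tuple[float, float] = (1e-3, 1e3),
    restarts: int = 10,
    seed: int = 0,
) -> KrigingModel:
    """Fit an ordinary-Kriging model by concentrated-likelihood multistart.

    ``theta_bounds`` bound each correlation hyperparameter on the unit-cube
    coordinate scale; the search runs in log space from ``restarts`` seeded
    starting points and keeps the best local optimum.
    """
    x = training.design.points
    y = training.responses
    if len(x) < 2:
        raise ValueError("Kriging needs at least 2 training points")
    space = training.design.space
    x_unit = space.scale(x)
    # coincident design points with conflicting responses are unfittable:
    # the interpolation conditions contradict each other
    d2 = np.sum((x_unit[:, None, :] - x_unit[None, :, :]) ** 2, axis=-1)
    yspan = max(np.ptp(y), 1.0)
    ii, jj = np.where(np.triu(d2 < 1e-20, k=1))
    for i, j in zip(ii, jj):
        if abs(y[i] - y[j]) > 1e-9 * yspan:
            raise ValueError(
                f"duplicate design points at rows ({i}, {j}) have "
                f"conflicting responses ({y[i]}, {y[j]})"
            )
    lo, hi = np.log(theta_bounds[0]), np.log(theta_bounds[1])
    rng = np.random.default_rng(seed)
    d = space.dimension

    starts = [np.full(d, np.log(10.0)).clip(lo, hi)]
    starts += [rng.uniform(lo, hi, size=d) for _ in range(max(0, restarts - 1))]

    best = None
    for nugget_scale in (1.0, 10.0, 100.0, 1000.0, 10000.0):
        nugget = min(_NUGGET * nugget_scale, _NUGGET_CAP)
        for s in starts:
            res = optimize.minimize(
                _neg_concentrated_loglik,
                s,
                args=(x_unit, y, nugget),
                method="L-BFGS-B",
                bounds=[(lo, hi)] * d,
            )
            if np.isfinite(res.fun) and res.fun < 1e29:
                if best is None or res.fun < best[0]:
                    best = (res.fun, res.x, nugget)
        if best is not None:
            break
    if best is None:
        raise linalg.LinAlgError(
            "correlation matrix singular for all hyperparameters even at "
            f"maximum nugget {_NUGGET_CAP}"
        )
    theta = np.exp(best[1])
    return _assemble(training, x_unit, theta, best[2])


def fit_fixed_theta(training: TrainingSet, theta, nugget: float = _NUGGET) -> KrigingModel:
    """Build the model at user-supplied hyperparameters (no estimation)."""
    theta = np.broadcast_to(np.asarray(theta, float), (training.design.space.dimension,))
    x_unit = training.design.space.scale(training.design.points)
    return _assemble(training, x_unit, np.array(theta, float), nugget)


def _assemble(training, x_unit, theta, nugget) -> KrigingModel:
    y = training.responses
    n = len(y)
    r = _corr_matrix(x_unit, theta, nugget)
    chol = linalg.cholesky(r, lower=True)
    one = np.ones(n)
    rinv_y = linalg.cho_solve((chol, True), y)
    rinv_one = linalg.cho_solve((chol, True), one)
    one_rinv_one = float(one @ rinv_one)
    mu = float(one @ rinv_y) / one_rinv_one
    resid = y - mu
    alpha = linalg.cho_solve((chol, True), resid)
    sigma2 = max(float(resid @ alpha) / n, _VAR_FLOOR)
    return KrigingModel(
        training=training,
        theta=theta,
        process_mean=mu,
        process_variance=sigma2,
        nugget=nugget,
        _chol=chol,
        _alpha=alpha,
        _rinv_one=rinv_one,
        _one_rinv_one=one_rinv_one,
        _x_unit=x_unit,
    )


def predict(model: KrigingModel, point) -> Prediction:
    """BLUP mean and predictive variance at a point (native units)."""
    space = model.space
    x = np.asarray(point, dtype=float).ravel()
    if x.shape != (space.dimension,):
        raise ValueError(
            f"point has dimension {x.shape[0] if x.ndim else 0}, "
            f"space has {space.dimension}"
        )
    extrapolating = not space.contains(x)
    pu = space.scale(x)[0]
    r = _corr_vector(model._x_unit, pu, model.theta)
    mean = model.process_mean + float(r @ model._alpha)
    rinv_r = linalg.cho_solve((model._chol, True), r)
    var = model.process_variance * (
        1.0 + model.nugget
        - float(r @ rinv_r)
        + (1.0 - float(r @ model._rinv_one)) ** 2 / model._one_rinv_one
    )
    return Prediction(mean=mean, variance=max(var, 0.0), extrapolating=extrapolating)
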