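"""Closed-form stand-ins for the finite-element evaluators.

The optimization pipeline treats the structural solver as a black box:
stent geometry -> nodal stress field, or balloon length -> expansion
history.  These toy models reproduce the qualitative response structure of
those solvers with cheap analytic expressions whose optima are known by
construction, so the whole adaptive loop can be exercised and its answers
checked exactly.  They carry no physical fidelity to any real device.

Fatigue model.  An effective stiffness coordinate t(x) grows with strut
width and thickness.  Mean stress rises with stiffness (stiffer struts carry
more of the deployment load), while the cyclic amplitude falls with it but
grows with any deviation from a designated geometry x*:

    sigma_m(x) = sigma_m* exp(a t(x)),
    sigma_a(x) = sigma_a* exp(-b t(x) + c |u(x)|^2),

with u the normalized deviation from x* and t = w . u.  The constants are
balanced (a sigma_m*/sigma_UTS = b sigma_a*/sigma_N) so the Goodman safety
distance has its unique interior maximum exactly at x*.  A designated worst
node carries the full stress; the remaining nodes are scaled-down copies,
so the set-level shortest distance is always governed by the same node and
the closed-form optimum survives the min over nodes.

Balloon model.  Both ends follow the trapezoidal pressure pulse with an
accelerating ramp, a plateau and a small elastic recoil on unloading; the
distal gain varies linearly with balloon length and crosses the proximal
gain exactly at L*, so the dogboning ratio at peak inflation is a strictly
increasing function of length with a single sign change at L*: spindle
(negative) at the lower bound, dogbone (positive) at the upper bound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .design_space import DesignSpace, make_space
from .expansion_metrics import ExpansionHistory, PressureProfile, pressure_at
from .fatigue_goodman import (
    STAINLESS_304,
    GoodmanMaterial,
    StressPoint,
    StressPointSet,
    goodman_margin,
)

__all__ = [
    "ToyFatigueModel",
    "ToyBalloonModel",
    "toy_fatigue_evaluate",
    "toy_balloon_evaluate",
    "standard_test_functions",
    "diamond_fatigue_space",
    "sv_fatigue_space",
]


def diamond_fatigue_space() -> DesignSpace:
    """Strut widths w1, w2 and thickness t1 of the diamond-shaped platform."""
    return make_space([("w1", 0.22, 0.34), ("w2", 0.2, 0.3), ("t1", 0.1, 0.14)])


def sv_fatigue_space() -> DesignSpace:
    """Strut width w3, chamfer radius R and thickness t2 of the sv platform."""
    return make_space([("w3", 0.08, 0.12), ("R", 0.08, 0.15), ("t2", 0.22, 0.34)])


@dataclass(frozen=True)
class ToyFatigueModel:
    """Analytic stent-fatigue stress field with a constructed optimum x*."""

    space: DesignSpace
    x_star: np.ndarray            # interior optimum, native units
    material: GoodmanMaterial = STAINLESS_304
    sigma_m_star: float = 304.6   # MPa, mean stress at x*
    sigma_a_star: float = 22.02   # MPa, amplitude at x*
    stiffness_gain: float = 0.4   # b: amplitude decay per unit stiffness
    curvature: float = 0.5        # c: deviation penalty in log amplitude
    n_nodes: int = 25
    node_seed: int = 1234

    def __post_init__(self) -> None:
        xs = np.asarray(self.x_star, dtype=float)
        object.__setattr__(self, "x_star", xs)
        self.space.validate_point(xs)
        lo, hi = self.space.lower, self.space.upper
        if np.any(xs <= lo) or np.any(xs >= hi):
            raise ValueError("x_star must lie strictly inside the bounds")
        if self.n_nodes < 1:
            raise ValueError("need at least one node")

    @property
    def _a(self) -> float:
        # balance condition making x* the stationary point of the margin
        m = self.material
        return (self.stiffness_gain
                * (self.sigma_a_star / m.sigma_N)
                / (self.sigma_m_star / m.sigma_UTS))

    @property
    def _weights(self) -> np.ndarray:
        d = self.space.dimension
        return np.full(d, 1.0 / math.sqrt(d))

    def _node_scales(self) -> np.ndarray:
        rng = np.random.default_rng(self.node_seed)
        scales = np.empty(self.n_nodes)
        scales[0] = 1.0  # the governing node
        if self.n_nodes > 1:
            scales[1:] = rng.uniform(0.70, 0.95, size=self.n_nodes - 1)
        return scales

    def stresses(self, x) -> tuple[float, float]:
        """(sigma_m, sigma_a) of the governing node at a design point."""
        xv = self.space.validate_point(x)
        u = (xv - self.x_star) / (self.space.upper - self.space.lower)
        t = float(self._weights @ u)
        sigma_m = self.sigma_m_star * math.exp(self._a * t)
        sigma_a = self.sigma_a_star * math.exp(
            -self.stiffness_gain * t + self.curvature * float(u @ u)
        )
        return sigma_m, sigma_a

    @property
    def optimum_margin(self) -> float:
        """Safety distance D* at the constructed optimum."""
        d, _ = goodman_margin(
            StressPoint(sigma_m=self.sigma_m_star, sigma_a=self.sigma_a_star),
            self.material,
        )
        return d

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": [list(v) for v in self.space.variables],
                "x_star": self.x_star.tolist(),
                "sigma_m_star": self.sigma_m_star,
                "sigma_a_star": self.sigma_a_star,
                "stiffness_gain": self.stiffness_gain,
                "curvature": self.curvature,
                "n_nodes": self.n_nodes,
                "node_seed": self.node_seed,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ToyFatigueModel":
        d = json.loads(payload)
        return cls(
            space=make_space(d["variables"]),
            x_star=np.asarray(d["x_star"], float),
            sigma_m_star=d["sigma_m_star"],
            sigma_a_star=d["sigma_a_star"],
            stiffness_gain=d["stiffness_gain"],
            curvature=d["curvature"],
            n_nodes=d["n_nodes"],
            node_seed=d["node_seed"],
        )

    @classmethod
    def diamond(cls) -> "ToyFatigueModel":
        space = diamond_fatigue_space()
        # interior optimum off the midpoint in every coordinate
        x_star = space.lower + np.array([0.45, 0.6, 0.4]) * (space.upper - space.lower)
        return cls(space=space, x_star=x_star)

    @classmethod
    def sv(cls) -> "ToyFatigueModel":
        space = sv_fatigue_space()
        x_star = space.lower + np.array([0.55, 0.4, 0.6]) * (space.upper - space.lower)
        return cls(space=space, x_star=x_star)


def toy_fatigue_evaluate(model: ToyFatigueModel, x) -> StressPointSet:
    """Deterministic nodal stress field at a design point."""
    sigma_m, sigma_a = model.stresses(x)
    scales = model._node_scales()
    points = tuple(
        StressPoint(sigma_m=s * sigma_m, sigma_a=s * sigma_a, node_id=i)
        for i, s in enumerate(scales)
    )
    return StressPointSet(points=points)


@dataclass(frozen=True)
class ToyBalloonModel:
    """Analytic balloon-length response with a known zero-dogboning length."""

    length_bounds: tuple[float, float]
    L_star: float | None = None        # defaults to the interval midpoint
    r0: float = 0.6                    # crimped radius, mm
    L0: float = 8.68                   # stent length, mm
    p_nominal: float = 1.2             # MPa reaching nominal diameter
    gain: float = 1.4                  # mm radial displacement per (p/p_nominal)
    dogboning_span: float = 0.12       # dogboning ratio swing across the interval
    recoil_fraction: float = 0.05      # elastic recoil of the peak displacement
    foreshortening_gain: float = 0.02  # axial shortening per mm displacement

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        if not lo < hi:
            raise ValueError("length bounds must satisfy lo < hi")
        if self.L_star is None:
            object.__setattr__(self, "L_star", 0.5 * (lo + hi))
        if not lo < self.L_star < hi:
            raise ValueError("L_star must lie inside the length bounds")

    def distal_gain(self, L: float) -> float:
        lo, hi = self.length_bounds
        return 1.0 + self.dogboning_span * (L - self.L_star) / (hi - lo)

    @classmethod
    def diamond(cls) -> "ToyBalloonModel":
        return cls(length_bounds=(4.6, 5.1), r0=0.6, L0=8.68)

    @classmethod
    def sv(cls) -> "ToyBalloonModel":
        return cls(length_bounds=(6.0, 6.5), r0=0.45, L0=6.05)


def toy_balloon_evaluate(
    model: ToyBalloonModel,
    L: float,
    p_max: float | None = None,
    dt: float = 1.0,
) -> ExpansionHistory:
    """Expansion history of the toy stent for one balloon length.

    Both ends track the pressure pulse with an accelerating loading ramp
    (displacement grows with the square of the normalized pressure during
    loading), hold their peak during the 25-32 ms plateau, and keep the
    plastic part of the displacement after unloading, shedding only the
    elastic ``recoil_fraction``.  The distal end's gain depends linearly on
    balloon length.
    """
    lo, hi = model.length_bounds
    if not lo <= L <= hi:
        raise ValueError(f"balloon length {L} outside [{lo}, {hi}]")
    if p_max is None:
        p_max = model.p_nominal
    profile = PressureProfile(p_max=p_max)
    times = np.arange(0.0, profile.t_unload_end + 0.5 * dt, dt)
    if not any(np.isclose(times, profile.t_hold_end)):
        times = np.sort(np.append(times, profile.t_hold_end))
    if not any(np.isclose(times, profile.t_unload_end)):
        times = np.sort(np.append(times, profile.t_unload_end))

    d_peak = model.gain * p_max / model.p_nominal
    g_dist = model.distal_gain(L)

    def drive(t: float) -> float:
        # accelerating expansion while loading, plateau, then elastic recoil
        if t <= profile.t_hold_end:
            p = pressure_at(profile, t) / p_max
            return p * p
        frac = (t - profile.t_hold_end) / (profile.t_unload_end - profile.t_hold_end)
        return 1.0 - model.recoil_fraction * frac

    m = np.array([drive(t) for t in times])
    d_prox = d_peak * m
    d_dist = d_peak * g_dist * m

    return ExpansionHistory(
        times=times,
        r_proximal=model.r0 + d_prox,
        r_distal=model.r0 + d_dist,
        length=model.L0 - model.foreshortening_gain * d_peak * m,
        r0=model.r0,
        L0=model.L0,
    )


_BRANIN_MIN = 0.39788735772973816


def _branin(x) -> float:
    x1, x2 = float(x[0]), float(x[1])
    a, b, c = 1.0, 5.1 / (4 * math.pi**2), 5.0 / math.pi
    r, s, t = 6.0, 10.0, 1.0 / (8 * math.pi)
    return (a * (x2 - b * x1**2 + c * x1 - r) ** 2
            + s * (1 - t) * math.cos(x1) + s)


def _forrester(x) -> float:
    z = float(np.asarray(x).ravel()[0])
    return (6 * z - 2) ** 2 * math.sin(12 * z - 4)


@dataclass(frozen=True)
class TestFunction:
    name: str
    space: DesignSpace
    func: object
    argmin: tuple[tuple[float, ...], ...]
    fmin: float

    def __call__(self, x) -> float:
        return self.func(x)


def standard_test_functions() -> dict[str, TestFunction]:
    """Registry of analytic objectives with known minima for validation."""
    registry = {
        "quadratic1d": TestFunction(
            name="quadratic1d",
            space=make_space([("x", 0.0, 1.0)]),
            func=lambda x: (float(np.asarray(x).ravel()[0]) - 0.3) ** 2,
            argmin=((0.3,),),
            fmin=0.0,
        ),
        "forrester1d": TestFunction(
            name="forrester1d",
            space=make_space([("x", 0.0, 1.0)]),
            func=_forrester,
            argmin=((0.757249,),),
            fmin=-6.020740,
        ),
        "branin": TestFunction(
            name="branin",
            space=make_space([("x1", -5.0, 10.0), ("x2", 0.0, 15.0)]),
            func=_branin,
            argmin=((-math.pi, 12.275), (math.pi, 2.275), (9.42478, 2.475)),
            fmin=_BRANIN_MIN,
        ),
    }
    return registry


def get_test_function(name: str) -> TestFunction:
    registry = standard_test_functions()
    if name not in registry:
        raise KeyError(
            f"unknown test function {name!r}; available: {sorted(registry)}"
        )
    return registry[name]
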