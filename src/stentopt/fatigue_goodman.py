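"""Goodman-diagram fatigue safety assessment.

Pulsatile arterial loading exposes every node of a deployed stent to a
cyclic stress described by its mean sigma_m = (sigma_sys + sigma_dia)/2 and
amplitude sigma_a = |sigma_sys - sigma_dia|/2.  On the Goodman diagram
(sigma_m on the abscissa, sigma_a on the ordinate) the failure line

    sigma_a / sigma_N + sigma_m / sigma_UTS = 1

separates safe states (below) from failure-prone ones, where sigma_N is the
material's endurance limit and sigma_UTS its ultimate tensile strength.  The
fatigue safety of a design is quantified by the shortest Euclidean distance
from its stress points to that line; maximising this shortest distance over
the stent geometry, subject to every node staying below the line, is the
fatigue design problem this module phrases for the optimizer.

All stresses are handled in MPa internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GoodmanMaterial",
    "StressPoint",
    "StressPointSet",
    "STAINLESS_304",
    "mean_amplitude",
    "goodman_margin",
    "shortest_distance",
    "fatigue_objective",
]


@dataclass(frozen=True)
class GoodmanMaterial:
    """Fatigue constants of the stent material, in MPa."""

    sigma_N: float
    sigma_UTS: float
    sigma_yield: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_N <= 0 or self.sigma_UTS <= 0:
            raise ValueError("material constants must be positive")
        if self.sigma_N >= self.sigma_UTS:
            raise ValueError("endurance limit must be below ultimate strength")

    @classmethod
    def from_gpa(cls, sigma_N, sigma_UTS, sigma_yield=None) -> "GoodmanMaterial":
        return cls(
            sigma_N=sigma_N * 1e3,
            sigma_UTS=sigma_UTS * 1e3,
            sigma_yield=None if sigma_yield is None else sigma_yield * 1e3,
        )


#: 316/304-grade stainless steel used for balloon-expandable stent platforms:
#: endurance limit 115 MPa, ultimate tensile strength 580 MPa, yield 315 MPa.
STAINLESS_304 = GoodmanMaterial.from_gpa(sigma_N=0.115, sigma_UTS=0.58,
                                         sigma_yield=0.315)


@dataclass(frozen=True)
class StressPoint:
    sigma_m: float
    sigma_a: float
    node_id: int | str | None = None

    def __post_init__(self) -> None:
        if self.sigma_a < 0:
            raise ValueError("stress amplitude cannot be negative")


@dataclass(frozen=True)
class StressPointSet:
    points: tuple[StressPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": [p.node_id for p in self.points],
                "sigma_m": [p.sigma_m for p in self.points],
                "sigma_a": [p.sigma_a for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StressPointSet":
        """Load nodal stresses from CSV.

        Accepts either mean/amplitude columns (sigma_m, sigma_a) or raw
        systolic/diastolic columns (sigma_systolic, sigma_diastolic);
        the header decides.  An optional node_id column is carried along.
        """
        df = pd.read_csv(path)
        cols = set(df.columns)
        ids = df["node_id"] if "node_id" in cols else range(len(df))
        if {"sigma_m", "sigma_a"} <= cols:
            pts = [
                StressPoint(sigma_m=m, sigma_a=a, node_id=i)
                for i, m, a in zip(ids, df["sigma_m"], df["sigma_a"])
            ]
        elif {"sigma_systolic", "sigma_diastolic"} <= cols:
            pts = [
                mean_amplitude(s, d, node_id=i)
                for i, s, d in zip(ids, df["sigma_systolic"], df["sigma_diastolic"])
            ]
        else:
            raise ValueError(
                "CSV must contain either (sigma_m, sigma_a) or "
                "(sigma_systolic, sigma_diastolic) columns"
            )
        return cls(points=tuple(pts))

    def goodman_export(self, material: GoodmanMaterial) -> pd.DataFrame:
        """Diagram-ready table: stress points plus the failure-line endpoints."""
        df = self.to_frame()
        df["kind"] = "node"
        line = pd.DataFrame(
            {
                "node_id": [None, None],
                "sigma_m": [material.sigma_UTS, 0.0],
                "sigma_a": [0.0, material.sigma_N],
                "kind": ["failure_line", "failure_line"],
            }
        )
        return pd.concat([df, line], ignore_index=True)


def mean_amplitude(sigma_systolic: float, sigma_diastolic: float,
                   node_id=None) -> StressPoint:
    """Decompose a systolic/diastolic stress pair into mean and amplitude."""
    s, d = float(sigma_systolic), float(sigma_diastolic)
    if not (math.isfinite(s) and math.isfinite(d)):
        raise ValueError("stresses must be finite")
    return StressPoint(sigma_m=(s + d) / 2.0, sigma_a=abs(s - d) / 2.0,
                       node_id=node_id)


def goodman_margin(
    point: StressPoint,
    material: GoodmanMaterial,
    normalized: bool = False,
) -> tuple[float, bool]:
    """Signed distance from a stress point to the Goodman failure line.

    Positive below the line (safe), zero on it, negative above (unsafe);
    safety and the sign of the distance always agree.  By default the
    distance is Euclidean in raw (sigma_m, sigma_a) MPa coordinates; with
    ``normalized=True`` it is measured in the dimensionless coordinates
    (sigma_m/sigma_UTS, sigma_a/sigma_N), where the failure line is
    x + y = 1.
    """
    slack = 1.0 - point.sigma_m / material.sigma_UTS - point.sigma_a / material.sigma_N
    if normalized:
        distance = slack / math.sqrt(2.0)
    else:
        distance = slack / math.hypot(1.0 / material.sigma_UTS,
                                      1.0 / material.sigma_N)
    return distance, slack >= 0.0


def shortest_distance(
    point_set: StressPointSet,
    material: GoodmanMaterial,
    normalized: bool = False,
) -> tuple[float, int | str | None]:
    """Minimum signed Goodman margin over a node set, with the worst node.

    A negative result means at least one node violates the failure line.
    """
    if len(point_set) == 0:
        raise ValueError("stress point set is empty")
    best = None
    worst_node = None
    for p in point_set:
        d, _ = goodman_margin(p, material, normalized=normalized)
        if best is None or d < best:
            best = d
            worst_node = p.node_id
    return float(best), worst_node


def fatigue_objective(
    stress_field_evaluator,
    material: GoodmanMaterial,
    penalty: float = 10.0,
    normalized: bool = False,
):
    """Wrap a stress-field evaluator into a scalar minimisation objective.

    The returned callable maps a design point to ``-D_shortest`` so that
    minimising it maximises the fatigue safety distance.  Designs with any
    node above the failure line are infeasible: they receive the worst
    feasible objective seen so far plus ``penalty`` times the constraint
    violation, which keeps the surrogate single-output while ordering every
    infeasible design behind every feasible one.
    """
    state = {"worst_feasible": 0.0, "seen_feasible": False}

    def objective(x) -> float:
        point_set = stress_field_evaluator(x)
        d, _ = shortest_distance(point_set, material, normalized=normalized)
        if d >= 0.0:
            value = -d
            if not state["seen_feasible"] or value > state["worst_feasible"]:
                state["worst_feasible"] = value
                state["seen_feasible"] = True
            return value
        return state["worst_feasible"] + penalty * (-d)

    return objective
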