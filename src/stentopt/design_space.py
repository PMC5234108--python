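"""Bounded continuous design spaces and space-filling initial designs.

A design space is an ordered set of named, bounded, continuous variables
(stent strut widths and thicknesses, or the balloon length, in mm).  Initial
training designs for the surrogate are produced by a modified rectangular
grid (MRG): a full-factorial grid thinned to the requested size by greedy
maximin selection, with every boundary-lying coordinate then pulled into the
interior.  Moving boundary points inward gives the surrogate information
about the interior of the design region and breaks up replicated coordinate
values that a plain factorial grid would carry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpace",
    "SampleDesign",
    "make_space",
    "mrg_design",
]

# Full-factorial grids larger than this are refused up front: the MRG
# construction materialises the grid before thinning it.
_MAX_GRID_POINTS = 1_000_000


@dataclass(frozen=True)
class DesignSpace:
    """Ordered list of (name, lower, upper) continuous design variables."""

    variables: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.variables) == 0:
            raise ValueError("design space needs at least one variable")
        names = [v[0] for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        for name, lo, hi in self.variables:
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"non-finite bounds for variable {name!r}")
            if not lo < hi:
                raise ValueError(
                    f"variable {name!r}: lower bound {lo} must be < upper bound {hi}"
                )

    @property
    def dimension(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> list[str]:
        return [v[0] for v in self.variables]

    @property
    def lower(self) -> np.ndarray:
        return np.array([v[1] for v in self.variables], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([v[2] for v in self.variables], dtype=float)

    def contains(self, point: np.ndarray, atol: float = 1e-12) -> bool:
        x = np.asarray(point, dtype=float)
        if x.shape != (self.dimension,):
            return False
        span = self.upper - self.lower
        return bool(
            np.all(x >= self.lower - atol * span) and np.all(x <= self.upper + atol * span)
        )

    def validate_point(self, point: np.ndarray) -> np.ndarray:
        """Return the point as a float vector, or raise if shape/bounds fail."""
        x = np.asarray(point, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(
                f"point has shape {x.shape}, expected ({self.dimension},)"
            )
        if not self.contains(x):
            raise ValueError(f"point {x.tolist()} outside bounds")
        return x

    def scale(self, points: np.ndarray) -> np.ndarray:
        """Map native-unit coordinates onto the unit cube."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.lower) / (self.upper - self.lower)

    def unscale(self, unit_points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(unit_points, dtype=float))
        return self.lower + pts * (self.upper - self.lower)


@dataclass(frozen=True)
class SampleDesign:
    """A set of design points drawn from a space, tagged by the scheme used."""

    space: DesignSpace
    points: np.ndarray  # (n, d) in native units
    scheme: str = "explicit"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if pts.shape[1] != self.space.dimension:
            raise ValueError(
                f"points have dimension {pts.shape[1]}, space has {self.space.dimension}"
            )
        for row in pts:
            if not self.space.contains(row):
                raise ValueError(f"point {row.tolist()} outside bounds")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("design contains duplicate points")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=self.space.names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: DesignSpace, scheme: str = "explicit") -> "SampleDesign":
        df = pd.read_csv(path)
        missing = [n for n in space.names if n not in df.columns]
        if missing:
            raise ValueError(f"CSV missing variable columns: {missing}")
        return cls(space=space, points=df[space.names].to_numpy(float), scheme=scheme)


def make_space(variables) -> DesignSpace:
    """Build a validated design space from (name, lower, upper) triples."""
    return DesignSpace(tuple((str(n), float(lo), float(hi)) for n, lo, hi in variables))


def _factorial_grid(space: DesignSpace, n: int) -> np.ndarray:
    """Smallest symmetric full-factorial grid (unit cube) with >= n points."""
    d = space.dimension
    m = 2
    while m ** d < n:
        m += 1
    if m ** d > _MAX_GRID_POINTS:
        achievable = [k ** d for k in range(2, m) if k ** d <= _MAX_GRID_POINTS]
        raise ValueError(
            f"grid of {m}^{d} points exceeds the supported size; "
            f"achievable factorial counts for dimension {d}: {achievable or 'none'}"
        )
    levels = np.linspace(0.0, 1.0, m)
    return np.array(list(itertools.product(*[levels] * d)), dtype=float)


def _maximin_subset(grid: np.ndarray, n: int) -> np.ndarray:
    """Greedy maximin thinning: start from the farthest pair, then repeatedly
    add the grid point whose nearest selected neighbour is farthest away.
    Deterministic (ties broken by index)."""
    if len(grid) == n:
        return grid.copy()
    d2 = np.sum((grid[:, None, :] - grid[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [int(i), int(j)]
    mind2 = np.minimum(d2[i], d2[j])
    while len(chosen) < n:
        mind2[chosen] = -np.inf
        k = int(np.argmax(mind2))
        chosen.append(k)
        mind2 = np.minimum(mind2, d2[k])
    return grid[np.sort(chosen)]


def mrg_design(
    space: DesignSpace,
    n: int,
    shrink: float = 0.1,
    seed: int = 0,
) -> SampleDesign:
    """Modified-rectangular-grid initial design.

    A full-factorial grid with the smallest per-axis level count whose size
    reaches ``n`` is thinned to ``n`` points by greedy maximin selection.
    With ``shrink`` > 0 every coordinate sitting on a bound is then moved
    into the interior by ``shrink`` times the variable's range, plus a small
    seeded inward jitter (at most 1% of the range) that breaks replicated
    coordinate values.  ``shrink`` = 0 returns the unmodified grid subset.

    Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("an initial design needs at least 2 points")
    if not 0.0 <= shrink < 0.5:
        raise ValueError("shrink must satisfy 0 <= shrink < 0.5")
    grid = _factorial_grid(space, n)
    unit = _maximin_subset(grid, n)

    if shrink > 0.0:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(0.0, 0.01, size=unit.shape)
        at_lower = unit <= 0.0
        at_upper = unit >= 1.0
        unit = unit + at_lower * (shrink + jitter) - at_upper * (shrink + jitter)

    return SampleDesign(space=space, points=space.unscale(unit), scheme="mrg")
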