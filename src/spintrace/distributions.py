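"""Distance grids and distance distributions.

The central currency of the package is ``DistanceDistribution``: a probability
density P(r) over inter-spin distance r (nm), stored per-nm on a uniform grid
and normalized so that the trapezoid integral over the grid equals 1.  Both
the DEER inversion and the structure-model prediction emit this type, which is
what makes them directly comparable (see :func:`overlap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceGrid",
    "DistanceDistribution",
    "make_grid",
    "overlap",
]

#: Hard physical bounds for spin-pair distances resolvable by DEER (nm).
R_MIN_ALLOWED = 1.0
R_MAX_ALLOWED = 12.0
MIN_GRID_POINTS = 64


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform, ascending grid of inter-spin distances in nm."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 1 or r.size < MIN_GRID_POINTS:
            raise ValueError(f"distance grid needs >= {MIN_GRID_POINTS} points")
        dr = np.diff(r)
        if np.any(dr <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if not np.allclose(dr, dr[0], rtol=1e-5):  # tolerate file round-trip
            raise ValueError("distance grid must be uniformly spaced")
        if r[0] < R_MIN_ALLOWED or r[-1] > R_MAX_ALLOWED:
            raise ValueError(
                f"distance grid must lie within [{R_MIN_ALLOWED}, {R_MAX_ALLOWED}] nm"
            )

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    def trapezoid_weights(self) -> np.ndarray:
        """Quadrature weights w such that w @ f == trapz(f, r)."""
        w = np.full(self.n, self.dr)
        w[0] *= 0.5
        w[-1] *= 0.5
        return w


def make_grid(r_min: float = 1.5, r_max: float = 8.0, n: int = 128) -> DistanceGrid:
    return DistanceGrid(np.linspace(r_min, r_max, n))


@dataclass
class DistanceDistribution:
    """Probability density over a :class:`DistanceGrid` (units 1/nm).

    The density is non-negative and trapezoid-normalized to unit integral.
    Construction normalizes automatically; pass ``normalize=False`` to keep
    raw values (e.g. for intermediate arithmetic).
    """

    grid: DistanceGrid
    density: np.ndarray
    normalize: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.shape != self.grid.r.shape:
            raise ValueError("density and grid shapes differ")
        if np.any(d < -1e-12 * max(1.0, np.abs(d).max())):
            raise ValueError("density must be non-negative")
        d = np.clip(d, 0.0, None)
        if self.normalize:
            total = np.trapezoid(d, self.grid.r)
            if total <= 0:
                raise ValueError("cannot normalize a zero-mass density")
            d = d / total
        self.density = d

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid.r))

    def mean(self) -> float:
        return float(np.trapezoid(self.density * self.grid.r, self.grid.r))

    def std(self) -> float:
        m = self.mean()
        var = np.trapezoid(self.density * (self.grid.r - m) ** 2, self.grid.r)
        return float(np.sqrt(max(var, 0.0)))

    def mode(self) -> float:
        return float(self.grid.r[int(np.argmax(self.density))])

    def n_modes(self, rel_height: float = 0.05) -> int:
        """Count local maxima exceeding ``rel_height`` of the global peak."""
        d = self.density
        floor = rel_height * d.max()
        interior = (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:]) & (d[1:-1] > floor)
        return int(np.count_nonzero(interior))


def resample(p: DistanceDistribution, grid: DistanceGrid) -> DistanceDistribution:
    """Linearly interpolate a distribution onto another grid and renormalize."""
    density = np.interp(grid.r, p.grid.r, p.density, left=0.0, right=0.0)
    return DistanceDistribution(grid, density)


def overlap(p: DistanceDistribution, q: DistanceDistribution) -> float:
    """Overlap integral ∫ min(P, Q) dr of two distributions on a shared grid.

    Equals 1 for identical distributions and 0 for disjoint support.
    """
    if not np.allclose(p.grid.r, q.grid.r):
        raise ValueError("distributions must share a grid")
    return float(np.trapezoid(np.minimum(p.density, q.density), p.grid.r))
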