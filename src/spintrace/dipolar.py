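"""Forward physics of four-pulse DEER.

A pair of nitroxide spin labels separated by a distance r couples through the
magnetic dipole-dipole interaction with frequency nu_dd = D / r^3.  Averaging
the dipolar modulation cos[(1 - 3 z^2) * 2 pi nu_dd t] over a powder of
molecular orientations (z = cos theta uniform on [0, 1]) gives the DEER
kernel K(t, r).  A measured trace is

    V(t) = [(1 - lambda) + lambda * (K p)] * B(t) + noise

where lambda is the modulation depth (fraction of the echo modulated by the
pumped spin), p the distance distribution sampled with trapezoid weights, and
B(t) the intermolecular background from the homogeneous spin bath, modelled
here as the stretched exponential exp(-k t^(d/3)).

Units are fixed package-wide: time in microseconds, distance in nm,
frequency in MHz.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import constants, special

from .distributions import DistanceDistribution, DistanceGrid

__all__ = [
    "DIPOLAR_CONSTANT_MHZ_NM3",
    "TimeGrid",
    "BackgroundModel",
    "DeerTrace",
    "dipolar_frequency",
    "kernel_matrix",
    "background",
    "simulate_deer",
    "form_factor",
    "write_trace",
    "read_trace",
]


def _dipolar_constant() -> float:
    """D = mu0 g^2 muB^2 / (4 pi h) in MHz nm^3, from CODATA constants.

    Uses the free-electron g-factor: the dipolar coupling between two S=1/2
    electron spins is governed by g_e, independent of the nitroxide's
    spectroscopic g-value.
    """
    g = abs(constants.physical_constants["electron g factor"][0])
    mu_b = constants.physical_constants["Bohr magneton"][0]
    d_si = constants.mu_0 * g**2 * mu_b**2 / (4 * np.pi * constants.h)  # Hz m^3
    return d_si * 1e21  # -> MHz nm^3


DIPOLAR_CONSTANT_MHZ_NM3 = _dipolar_constant()


def dipolar_frequency(r) -> np.ndarray | float:
    """Dipolar coupling frequency nu_dd = D / r^3 in MHz for r in nm."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = DIPOLAR_CONSTANT_MHZ_NM3 / r**3
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TimeGrid:
    """Dipolar evolution times t' in microseconds, starting at 0."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs >= 2 points")
        if abs(t[0]) > 1e-12:
            raise ValueError("time grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def t_max(self) -> float:
        return float(self.t[-1])


def default_time_grid(t_max: float = 4.0, dt: float = 0.016) -> TimeGrid:
    """Default acquisition window: 4 us dipolar evolution, 16 ns steps."""
    n = int(round(t_max / dt)) + 1
    return TimeGrid(np.linspace(0.0, t_max, n))


@dataclass(frozen=True)
class BackgroundModel:
    """Stretched-exponential intermolecular background B(t) = exp(-k t^(d/3)).

    ``d`` is the effective dimensionality of the surrounding spin bath
    (3 for a homogeneous solution); ``k`` the decay rate in us^(-d/3).
    """

    k: float
    d: float = 3.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("background decay rate k must be >= 0")
        if not 1.0 <= self.d <= 6.0:
            raise ValueError("background dimensionality d must be in [1, 6]")

    def __call__(self, t) -> np.ndarray:
        return background(t, self)


def background(t, model: BackgroundModel) -> np.ndarray:
    t = np.asarray(t, dtype=float) if not isinstance(t, TimeGrid) else t.t
    return np.exp(-model.k * np.abs(t) ** (model.d / 3.0))


@dataclass
class DeerTrace:
    """Echo-amplitude time trace V(t) with optional ground-truth metadata."""

    grid: TimeGrid
    amplitude: np.ndarray
    lam: float | None = None
    noise_sigma: float | None = None
    seed: int | None = None
    tau1: float = 0.4
    tau2: float = 4.0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.shape != self.grid.t.shape:
            raise ValueError("amplitude and time grid shapes differ")
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitude must be finite")
        self.amplitude = amp

    def normalized(self) -> "DeerTrace":
        """Rescale so V(0) = 1 (zero-time normalization)."""
        v0 = self.amplitude[0]
        if v0 == 0:
            raise ValueError("cannot normalize: V(0) = 0")
        return DeerTrace(
            self.grid, self.amplitude / v0, self.lam, self.noise_sigma,
            self.seed, self.tau1, self.tau2,
        )


def kernel_matrix(
    tgrid: TimeGrid, rgrid: DistanceGrid, method: str = "fresnel",
    quad_order: int = 1001,
) -> np.ndarray:
    """DEER powder-average kernel K[t, r], with K[0, r] = 1.

    K(t, r) = int_0^1 cos[(1 - 3 z^2) * omega t] dz,  omega = 2 pi nu_dd(r).

    ``method='fresnel'`` evaluates the closed form in terms of Fresnel sine
    and cosine integrals; ``method='quadrature'`` uses fixed-order
    Gauss-Legendre quadrature over z (the two agree to < 1e-6).
    """
    t = tgrid.t
    r = rgrid.r
    if t.size == 0 or r.size == 0:
        raise ValueError("empty grids")
    omega = 2 * np.pi * dipolar_frequency(r)  # rad/us, shape (nr,)
    phi = np.abs(t[:, None] * omega[None, :])  # (nt, nr)

    if method == "fresnel":
        K = np.ones_like(phi)
        nz = phi > 0
        ph = phi[nz]
        kappa = np.sqrt(6 * ph / np.pi)
        fs, fc = special.fresnel(kappa)
        K[nz] = np.sqrt(np.pi / (6 * ph)) * (np.cos(ph) * fc + np.sin(ph) * fs)
    elif method == "quadrature":
        z, w = np.polynomial.legendre.leggauss(quad_order)
        z = 0.5 * (z + 1.0)  # map to [0, 1]
        w = 0.5 * w
        # (nt, nr, nz) would be large; accumulate over z instead
        K = np.zeros_like(phi)
        for zi, wi in zip(z, w):
            K += wi * np.cos((1.0 - 3.0 * zi**2) * phi)
    else:
        raise ValueError(f"unknown kernel method {method!r}")
    K[0, :] = 1.0
    return K


def _mass_vector(p: DistanceDistribution) -> np.ndarray:
    """Trapezoid-weighted density so that sum equals the unit integral."""
    return p.grid.trapezoid_weights() * p.density


def simulate_deer(
    p: DistanceDistribution,
    lam: float,
    bg: BackgroundModel,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    tgrid: TimeGrid | None = None,
) -> DeerTrace:
    """Simulate a four-pulse DEER trace from a known distance distribution.

    V(t) = [(1 - lambda) + lambda * K p] * B(t) + eps,
    eps iid Gaussian(0, noise_sigma).  V(0) = 1 in the noiseless limit.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("modulation depth lambda must be in [0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if tgrid is None:
        tgrid = default_time_grid()
    K = kernel_matrix(tgrid, p.grid)
    mass = _mass_vector(p)
    mass = mass / mass.sum()  # exact K p = 1 at t = 0
    ff = K @ mass
    v = ((1.0 - lam) + lam * ff) * background(tgrid, bg)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma, size=v.shape)
    return DeerTrace(tgrid, v, lam=lam, noise_sigma=noise_sigma, seed=seed)


def form_factor(trace: DeerTrace, bg: BackgroundModel, lam: float) -> np.ndarray:
    """Background-divided, modulation-depth-normalized form factor.

    F(t) = V(t) / B(t);  the modulated part is rescaled to span [0, 1]:
    F~(t) = (F(t) - (1 - lambda)) / lambda.  For a noiseless trace this
    recovers K p exactly.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("modulation depth lambda must be in (0, 1]")
    b = background(trace.grid, bg)
    if np.any(b == 0):
        raise ValueError("background is zero somewhere on the time grid")
    f = trace.amplitude / b
    return (f - (1.0 - lam)) / lam


# --------------------------------------------------------------------------
# Trace file dialect: two-column ASCII (t [us], V) with '#' header lines.

def write_trace(path, trace: DeerTrace) -> None:
    path = Path(path)
    lines = ["# spintrace DEER trace", "# columns: t_us V"]
    for key in ("lam", "noise_sigma", "seed", "tau1", "tau2"):
        val = getattr(trace, key)
        if val is not None:
            lines.append(f"# {key} = {val}")
    body = "\n".join(f"{t:.9g}\t{v:.9g}" for t, v in zip(trace.grid.t, trace.amplitude))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path) -> DeerTrace:
    """Read a two-column trace; tolerates comma or whitespace separators."""
    path = Path(path)
    meta: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("#").partition("=")
                try:
                    meta[key.strip()] = float(val.strip())
                except ValueError:
                    pass
            continue
        parts = line.replace(",", " ").split()
        if len(parts) >= 2:
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows)
    seed = meta.get("seed")
    return DeerTrace(
        TimeGrid(arr[:, 0]),
        arr[:, 1],
        lam=meta.get("lam"),
        noise_sigma=meta.get("noise_sigma"),
        seed=int(seed) if seed is not None else None,
        tau1=meta.get("tau1", 0.4),
        tau2=meta.get("tau2", 4.0),
    )
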