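"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of data are generated:

* Gaussian-mixture distance distributions and the DEER traces they imply
  (via the forward model in :mod:`spintrace.dipolar`), emulating 4 us
  dipolar evolution windows at typical sensitivity;
* two-component nitroxide CW spectra: a sharp, mobile three-line pattern
  and a broad, immobilized pattern mixed by an immobilized fraction f,
  emulating the appearance of a slow-motion component upon binding;
* conformer ensembles of an ideal alpha-helix (or an unfolded random-coil
  control) with labeled sites at known inter-site distances.

Every generator is deterministic under a fixed seed and can emit a JSON
truth side-car next to its data files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import constants

from .cw import CwSpectrum
from .dipolar import BackgroundModel, DeerTrace, TimeGrid, default_time_grid, simulate_deer
from .distributions import DistanceDistribution, DistanceGrid, make_grid
from .structures import ConformerEnsemble

__all__ = [
    "GroundTruth",
    "CwGroundTruth",
    "make_pr",
    "make_deer_dataset",
    "make_cw_spectrum",
    "make_helix_ensemble",
    "helix_site_distance",
]

# Ideal alpha-helix geometry (nm, degrees per residue).
HELIX_RISE = 0.15
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 0.23
CBETA_RADIAL_OFFSET = 0.15  # pseudo C-beta displaced radially outward

# Nitroxide spectroscopic g-value: sets the CW spectral center field.
NITROXIDE_G = 2.0059


@dataclass
class GroundTruth:
    """Known truth behind a synthetic DEER dataset.

    ``pr_components`` lists (mean nm, sigma nm, weight); weights sum to 1.
    SNR 30 on a unit-amplitude trace corresponds to noise_sigma = 1/30.
    """

    pr_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(3.5, 0.3, 1.0)]
    )
    lam: float = 0.3
    background_k: float = 0.05
    background_d: float = 3.0
    noise_sigma: float = 1.0 / 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.pr_components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(c[1] <= 0 for c in self.pr_components):
            raise ValueError("component sigmas must be positive")


@dataclass
class CwGroundTruth:
    """Known truth behind a synthetic two-component CW spectrum.

    ``a_N`` is the effective splitting of the mobile triplet and
    ``A_zz_eff`` that of the immobilized one, both measured between the
    center field and the observable low-field extremum (gauss).
    """

    immobilized_fraction: float = 0.0
    a_N: float = 17.0
    A_zz_eff: float = 27.7
    mobile_linewidth: float = 1.5   # Lorentzian HWHM, G
    immobile_linewidth: float = 9.0  # Gaussian sigma, G
    g_value: float = NITROXIDE_G
    mw_frequency: float = 9.6355  # GHz
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobilized_fraction <= 1.0:
            raise ValueError("immobilized_fraction must be in [0, 1]")
        if not self.a_N < self.A_zz_eff:
            raise ValueError("a_N must be smaller than A_zz_eff")

    @property
    def center_field(self) -> float:
        """Resonance field B0 = h nu / (g muB), in gauss."""
        mu_b = constants.physical_constants["Bohr magneton"][0]
        b0_tesla = constants.h * self.mw_frequency * 1e9 / (self.g_value * mu_b)
        return b0_tesla * 1e4


def make_pr(
    components: list[tuple[float, float, float]],
    grid: DistanceGrid | None = None,
) -> DistanceDistribution:
    """Normalized Gaussian-mixture distance distribution on a grid."""
    if grid is None:
        grid = make_grid()
    density = np.zeros(grid.n)
    for mean, sigma, weight in components:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        density += weight * np.exp(-0.5 * ((grid.r - mean) / sigma) ** 2) / sigma
    return DistanceDistribution(grid, density)


def make_deer_dataset(
    truth: GroundTruth,
    tgrid: TimeGrid | None = None,
    rgrid: DistanceGrid | None = None,
    out_dir=None,
) -> tuple[DeerTrace, DistanceDistribution]:
    """Simulate a DEER trace from known truth; optionally write files.

    With ``out_dir`` set, emits ``trace.dat`` (the two-column trace dialect)
    and ``truth.json``.
    """
    if tgrid is None:
        tgrid = default_time_grid()
    p = make_pr(truth.pr_components, rgrid)
    bg = BackgroundModel(truth.background_k, truth.background_d)
    trace = simulate_deer(p, truth.lam, bg, truth.noise_sigma, truth.seed, tgrid)
    if out_dir is not None:
        from .dipolar import write_trace

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trace(out_dir / "trace.dat", trace)
        (out_dir / "truth.json").write_text(json.dumps(asdict(truth), indent=1))
    return trace, p


def _derivative_lorentzian(x: np.ndarray, gamma: float) -> np.ndarray:
    """Derivative of the unit-area Lorentzian absorption line."""
    return -(2.0 * gamma / np.pi) * x / (x**2 + gamma**2) ** 2


def _derivative_gaussian(x: np.ndarray, sigma: float) -> np.ndarray:
    """Derivative of the unit-area Gaussian absorption line."""
    return -x / (sigma**3 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * (x / sigma) ** 2)


def _baseline_window(field: np.ndarray, b0: float,
                     flat: float = 70.0, edge: float = 85.0) -> np.ndarray:
    """Cosine taper to compact support, emulating baseline-corrected spectra.

    Real CW spectra are baseline-corrected before analysis, so the field
    margins carry no signal; without the taper the slowly decaying
    Lorentzian tails would leak into the noise-estimation windows.
    """
    x = np.abs(field - b0)
    w = np.ones_like(field)
    ramp = (x > flat) & (x < edge)
    w[ramp] = 0.5 * (1 + np.cos(np.pi * (x[ramp] - flat) / (edge - flat)))
    w[x >= edge] = 0.0
    return w


def default_field_grid() -> np.ndarray:
    """3330-3530 G at 0.1 G steps: a typical X-band nitroxide span."""
    return np.arange(3330.0, 3530.0 + 1e-9, 0.1)


def make_cw_spectrum(
    truth: CwGroundTruth,
    field: np.ndarray | None = None,
) -> CwSpectrum:
    """Two-component first-derivative nitroxide spectrum.

    spectrum = (1 - f) * mobile + f * immobilized + noise.  The mobile
    component is a triplet of narrow derivative-Lorentzian lines, the
    immobilized one a triplet of broad derivative-Gaussian lines.  Line
    centers are offset by one derivative-extremum width so the observable
    low-field extrema fall at B0 - a_N and B0 - A_zz_eff (the splittings are
    "effective" peak splittings, matching how the landmark fields are read
    off a real spectrum).
    """
    if field is None:
        field = default_field_grid()
    field = np.asarray(field, dtype=float)
    b0 = truth.center_field
    gamma, sigma = truth.mobile_linewidth, truth.immobile_linewidth
    span = truth.A_zz_eff + 3 * max(gamma, sigma)
    if field[0] > b0 - span or field[-1] < b0 + span:
        raise ValueError(
            f"field grid must cover B0 +/- {span:.1f} G around {b0:.1f} G"
        )

    # outer (m_I = +/-1) lines of a tumbling nitroxide are broadened relative
    # to the center line by the partially averaged hyperfine anisotropy
    gamma_outer = 1.2 * gamma
    # extremum of a derivative Lorentzian sits gamma/sqrt(3) from its center,
    # of a derivative Gaussian sigma from its center
    off_m = gamma_outer / np.sqrt(3.0)
    off_i = sigma
    mobile = (
        _derivative_lorentzian(field - (b0 - truth.a_N + off_m), gamma_outer)
        + _derivative_lorentzian(field - b0, gamma)
        + _derivative_lorentzian(field - (b0 + truth.a_N - off_m), gamma_outer)
    ) / 3.0
    immobile_centers = (b0 - truth.A_zz_eff + off_i, b0, b0 + truth.A_zz_eff - off_i)
    immobile = sum(_derivative_gaussian(field - c, sigma) for c in immobile_centers) / 3.0

    f = truth.immobilized_fraction
    intensity = ((1.0 - f) * mobile + f * immobile) * _baseline_window(field, b0)
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        intensity = intensity + rng.normal(0.0, truth.noise_sigma, size=field.shape)
    return CwSpectrum(field, intensity, truth.mw_frequency)


def helix_site_distance(separation: int, radius: float = HELIX_RADIUS + CBETA_RADIAL_OFFSET) -> float:
    """Closed-form inter-site distance on an ideal helix for a residue offset.

    d = sqrt(2 R^2 (1 - cos(separation * twist)) + (separation * rise)^2),
    with R the radial position of the site reference atom (pseudo C-beta).
    """
    dtheta = np.deg2rad(HELIX_TWIST_DEG) * separation
    return float(
        np.sqrt(
            2 * radius**2 * (1 - np.cos(dtheta)) + (separation * HELIX_RISE) ** 2
        )
    )


def _ideal_helix(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha and pseudo C-beta coordinates of an ideal alpha helix (nm)."""
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    ca = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i],
        axis=1,
    )
    r_cb = HELIX_RADIUS + CBETA_RADIAL_OFFSET
    cb = np.stack(
        [r_cb * np.cos(theta), r_cb * np.sin(theta), HELIX_RISE * i], axis=1
    )
    return ca, cb


def _random_coil(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with the helical C-alpha step length."""
    step = np.linalg.norm(np.diff(_ideal_helix(2)[0], axis=0))
    min_sep = 0.35  # nm, excluded-volume clash distance
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = coords[i - 1] + step * direction
            if i < 2 or np.min(
                np.linalg.norm(coords[: i - 1] - candidate, axis=1)
            ) >= min_sep:
                coords[i] = candidate
                break
        else:  # accept a clash rather than fail; rare at these lengths
            coords[i] = candidate
    return coords


def make_helix_ensemble(
    n_residues: int = 40,
    site_pair: tuple[int, int] = (5, 25),
    n_frames: int = 200,
    jitter_sigma: float = 0.05,
    unfolded: bool = False,
    seed: int | None = None,
) -> ConformerEnsemble:
    """Conformer ensemble of an ideal alpha helix with two labeled sites.

    Frames are the ideal helix plus isotropic Gaussian coordinate jitter
    (``jitter_sigma`` per atom per axis); ``unfolded=True`` replaces the
    helix by an independent self-avoiding random walk per frame, emulating
    loss of secondary structure.  Residue numbering is 1-based.
    """
    i, j = site_pair
    if i == j:
        raise ValueError("labeled sites must differ")
    if not (1 <= i <= n_residues and 1 <= j <= n_residues):
        raise ValueError("sites must lie within the chain")
    rng = np.random.default_rng(seed)
    backbone = np.empty((n_frames, n_residues, 3))
    site_i = np.empty((n_frames, 3))
    site_j = np.empty((n_frames, 3))
    if unfolded:
        for m in range(n_frames):
            coil = _random_coil(n_residues, rng)
            backbone[m] = coil
            site_i[m] = coil[i - 1]
            site_j[m] = coil[j - 1]
    else:
        ca, cb = _ideal_helix(n_residues)
        for m in range(n_frames):
            jitter = rng.normal(0.0, jitter_sigma, size=ca.shape) if jitter_sigma > 0 else 0.0
            backbone[m] = ca + jitter
            cb_jit = cb + (jitter if jitter_sigma > 0 else 0.0)
            site_i[m] = cb_jit[i - 1]
            site_j[m] = cb_jit[j - 1]
    return ConformerEnsemble(backbone, {str(i): site_i, str(j): site_j})
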