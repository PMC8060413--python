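"""CW-EPR spectral preprocessing and the low-field peak ratio (LFPR).

A room-temperature nitroxide CW spectrum is the first derivative of the
absorption versus magnetic field.  When part of the label population is
rotationally immobilized (e.g. by contact with a binding partner), a broad
slow-motion component appears; its characteristic low-field feature sits a
few gauss below the sharp low-field line of the mobile component.  The LFPR
parameterizes this without a full lineshape simulation: it is the intensity
ratio at two fixed field positions, one on the mobile low-field peak and one
on the immobilized low-field peak, after rescaling the field axis to a common
microwave frequency and normalizing to the center-line maximum.  Ratios are
reported relative to a reference spectrum (the free protein in solution), and
the error bar is the baseline noise expressed relative to the peak intensity
in the ratio's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "CwSpectrum",
    "LfprResult",
    "rescale_field_axis",
    "normalize_center_peak",
    "smooth",
    "lfpr",
    "normalize_lfpr",
    "lfpr_error",
    "read_spectrum",
    "write_spectrum",
]

#: Microwave frequency all spectra are rescaled to before comparison (GHz).
REFERENCE_FREQUENCY_GHZ = 9.6355

#: Field positions (gauss) of the mobile and immobilized low-field peaks.
FIELD_MOBILE_G = 3415.3
FIELD_IMMOBILE_G = 3404.6

#: Half-width (gauss) of the search window around the center line.
CENTER_WINDOW_G = 8.0

#: Denominator floor below which the ratio is considered undefined.
INTENSITY_FLOOR = 1e-6


@dataclass(frozen=True)
class CwSpectrum:
    """First-derivative absorption spectrum over a field axis in gauss."""

    field: np.ndarray
    intensity: np.ndarray
    mw_frequency: float  # GHz

    def __post_init__(self) -> None:
        b = np.asarray(self.field, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "field", b)
        object.__setattr__(self, "intensity", i)
        if b.shape != i.shape or b.ndim != 1 or b.size < 201:
            raise ValueError("field and intensity must be 1-D, same length >= 201")
        if np.any(np.diff(b) <= 0):
            raise ValueError("field axis must be strictly increasing")
        if self.mw_frequency is not None and not 9.0 <= self.mw_frequency <= 10.0:
            raise ValueError("X-band microwave frequency must be in [9, 10] GHz")

    @property
    def n(self) -> int:
        return self.field.size


@dataclass(frozen=True)
class LfprResult:
    raw_ratio: float
    normalized_ratio: float
    error: float


def rescale_field_axis(
    s: CwSpectrum, ref_frequency: float = REFERENCE_FREQUENCY_GHZ
) -> CwSpectrum:
    """Rescale the field axis to a common microwave frequency.

    Resonance fields scale linearly with frequency at fixed g, so
    B' = B * (ref / mw_frequency) superimposes spectra recorded at slightly
    different frequencies without changing their g-values.
    """
    if s.mw_frequency is None:
        raise ValueError("spectrum has no microwave frequency metadata")
    factor = ref_frequency / s.mw_frequency
    return CwSpectrum(s.field * factor, s.intensity.copy(), ref_frequency)


def _center_crossing_index(s: CwSpectrum) -> int:
    """Index of the zero crossing of the central derivative feature.

    A first-derivative nitroxide pattern crosses the baseline between its
    global positive maximum (low-field side) and global negative minimum
    (high-field side); the first sign change after the maximum locates the
    spectral center for both sharp mobile and broad immobilized patterns.
    """
    i_max = int(np.argmax(s.intensity))
    i_min = int(np.argmin(s.intensity))
    hi = i_min if i_min > i_max else s.n
    sign = np.sign(s.intensity[i_max:hi])
    crossings = np.nonzero(sign <= 0)[0]
    if crossings.size == 0:
        return i_max
    return i_max + int(crossings[0])


def normalize_center_peak(s: CwSpectrum) -> CwSpectrum:
    """Scale the spectrum so the center-line maximum equals 1.

    The maximum is searched within +/- 8 G of the central line's zero
    crossing, making the normalization insensitive to low-field or baseline
    features.  The whole pipeline becomes scale-invariant in the raw
    intensity units after this step.
    """
    ic = _center_crossing_index(s)
    b0 = s.field[ic]
    window = np.abs(s.field - b0) <= CENTER_WINDOW_G
    peak = s.intensity[window].max() if window.any() else -np.inf
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("no positive center-peak maximum found")
    return CwSpectrum(s.field.copy(), s.intensity / peak, s.mw_frequency)


def smooth(s: CwSpectrum, order: int = 2, frame: int = 101) -> CwSpectrum:
    """Savitzky-Golay polynomial smoothing (default order 2, frame 101)."""
    if frame % 2 == 0 or frame <= order:
        raise ValueError("frame must be odd and > order")
    if frame >= s.n:
        raise ValueError("frame must be shorter than the spectrum")
    return CwSpectrum(
        s.field.copy(), savgol_filter(s.intensity, frame, order), s.mw_frequency
    )


def lfpr(
    s: CwSpectrum,
    field_mobile: float = FIELD_MOBILE_G,
    field_immobile: float = FIELD_IMMOBILE_G,
) -> float:
    """Raw low-field peak ratio I(field_mobile) / I(field_immobile).

    Intensities are linearly interpolated at the two field positions; the
    spectrum should be frequency-rescaled and center-normalized first.
    """
    lo, hi = s.field[0], s.field[-1]
    for f in (field_mobile, field_immobile):
        if not lo <= f <= hi:
            raise ValueError(f"field {f} G outside spectrum range [{lo}, {hi}] G")
    i_mob = float(np.interp(field_mobile, s.field, s.intensity))
    i_imm = float(np.interp(field_immobile, s.field, s.intensity))
    if abs(i_imm) < INTENSITY_FLOOR:
        raise ValueError(
            f"intensity at {field_immobile} G below {INTENSITY_FLOOR}: ratio undefined"
        )
    return i_mob / i_imm


def normalize_lfpr(sample: float, reference: float) -> float:
    """Normalize a raw ratio to the reference spectrum's raw ratio."""
    if reference == 0:
        raise ValueError("reference ratio is zero")
    return sample / reference


def lfpr_error(
    s: CwSpectrum,
    field_immobile: float = FIELD_IMMOBILE_G,
    baseline_fraction: float = 0.05,
) -> float:
    """Noise-based LFPR error bar.

    The noise level is the standard deviation of the intensity over the
    outermost ``baseline_fraction`` of the field axis on each side (the
    nitroxide signal is confined to the central ~80 G); the error is that
    noise relative to the intensity at the immobilized low-field peak, i.e.
    the denominator of the ratio.
    """
    n_edge = int(round(baseline_fraction * s.n))
    if n_edge < 10:
        raise ValueError("baseline window shorter than 10 points")
    baseline = np.concatenate([s.intensity[:n_edge], s.intensity[-n_edge:]])
    noise = float(np.std(baseline))
    i_imm = float(np.interp(field_immobile, s.field, s.intensity))
    if abs(i_imm) < INTENSITY_FLOOR:
        raise ValueError("peak intensity below floor: error undefined")
    return noise / abs(i_imm)


def analyze_lfpr(
    sample: CwSpectrum,
    reference: CwSpectrum,
    apply_smoothing: bool = False,
    field_mobile: float = FIELD_MOBILE_G,
    field_immobile: float = FIELD_IMMOBILE_G,
) -> LfprResult:
    """Full chain: rescale, normalize, (optionally smooth), ratio + error."""
    def prep(s: CwSpectrum) -> CwSpectrum:
        s = rescale_field_axis(s)
        s = normalize_center_peak(s)
        if apply_smoothing:
            s = smooth(s)
        return s

    samp, ref = prep(sample), prep(reference)
    raw = lfpr(samp, field_mobile, field_immobile)
    raw_ref = lfpr(ref, field_mobile, field_immobile)
    return LfprResult(
        raw_ratio=raw,
        normalized_ratio=normalize_lfpr(raw, raw_ref),
        error=lfpr_error(samp, field_immobile),
    )


# --------------------------------------------------------------------------
# Spectrum file dialect: two-column ASCII (B [G], intensity), '#' header.

def write_spectrum(path, s: CwSpectrum) -> None:
    path = Path(path)
    header = [
        "# spintrace CW spectrum",
        "# columns: field_G intensity",
        f"# mw_frequency = {s.mw_frequency}",
    ]
    body = "\n".join(f"{b:.6f}\t{i:.9g}" for b, i in zip(s.field, s.intensity))
    path.write_text("\n".join(header) + "\n" + body + "\n")


def read_spectrum(path) -> CwSpectrum:
    path = Path(path)
    freq = None
    rows: list[tuple[float, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "mw_frequency" in line and "=" in line:
                freq = float(line.split("=")[1])
            continue
        parts = line.replace(",", " ").split()
        if len(parts) >= 2:
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.asarray(rows)
    return CwSpectrum(arr[:, 0], arr[:, 1], freq)
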