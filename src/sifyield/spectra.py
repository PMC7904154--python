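"""Spectrum container and shared radiometric primitives.

All wavelengths are in nanometres. Spectral kinds and their units:

* ``irradiance``  -- W m^-2 nm^-1 (downwelling, cosine-corrected)
* ``radiance``    -- W m^-2 sr^-1 nm^-1 (upwelling, at-sensor)
* ``reflectance`` -- unitless reflectance factor

PAR is integrated in energy units (W m^-2); :func:`par_to_quantum` converts
to a photon flux for users who need mol-based units, but SIF yield is always
formed from the energy integral, making it a ratio with units sr^-1 um^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "BandWindow",
    "resample_spectrum",
    "band_mean",
    "ndvi",
    "integrate_par",
    "to_reflectance",
    "par_to_quantum",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

#: Red and NIR windows used by the NDVI definition, nm.
RED_WINDOW = (650.0, 660.0)
NIR_WINDOW = (770.0, 780.0)

#: PAR integration limits, nm.
PAR_RANGE = (400.0, 700.0)


class SpectrumKind(str, Enum):
    IRRADIANCE = "irradiance"
    RADIANCE = "radiance"
    REFLECTANCE = "reflectance"


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed radiometric samples with a declared kind."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = SpectrumKind.RADIANCE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D arrays")
        if wl.shape != vals.shape:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(wl)) or np.any(~np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite samples")
        kind = SpectrumKind(self.kind)
        if kind is SpectrumKind.REFLECTANCE and np.any(vals < 0):
            raise ValueError("reflectance spectrum has negative samples")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", kind)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def at(self, wavelength: float) -> float:
        """Value at the sample nearest to ``wavelength``."""
        return float(self.values[self.index_of(wavelength)])

    def index_of(self, wavelength: float) -> int:
        """Index of the band centre nearest to ``wavelength``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, kind or self.kind)


@dataclass(frozen=True)
class BandWindow:
    """Closed wavelength interval [lo, hi] on band centres."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths)
        return (wl >= self.lo) & (wl <= self.hi)


def resample_spectrum(s: Spectrum, target_wavelengths: np.ndarray) -> Spectrum:
    """Cubic-spline resample onto ``target_wavelengths`` (no extrapolation).

    Mirrors the resampling of ~0.35 nm spectrometer output onto the 2.1 nm
    camera grid.
    """
    targets = np.asarray(target_wavelengths, dtype=float)
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    outside = (targets < lo) | (targets > hi)
    if np.any(outside):
        bad = targets[outside][0]
        raise ValueError(
            f"target wavelength {bad:g} nm outside source support [{lo:g}, {hi:g}] nm"
        )
    if len(s) < 4:
        raise ValueError("need >= 4 samples for cubic resampling")
    spline = CubicSpline(s.wavelengths, s.values)
    values = spline(targets)
    if s.kind is SpectrumKind.REFLECTANCE:
        values = np.clip(values, 0.0, None)  # spline ringing must not go negative
    return Spectrum(targets, values, s.kind)


def band_mean(s: Spectrum, w: BandWindow) -> float:
    """Arithmetic mean of samples whose band centre lies in the closed window."""
    m = w.mask(s.wavelengths)
    if not np.any(m):
        raise ValueError(
            f"no band centres inside [{w.lo:g}, {w.hi:g}] nm "
            f"(support [{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}] nm)"
        )
    return float(np.mean(s.values[m]))


def ndvi(
    reflectance: Spectrum,
    nir_window: BandWindow | None = None,
    red_window: BandWindow | None = None,
) -> float:
    """(R_nir - R_red) / (R_nir + R_red) over the 770-780 / 650-660 nm windows."""
    nir_window = nir_window or BandWindow(*NIR_WINDOW)
    red_window = red_window or BandWindow(*RED_WINDOW)
    r_nir = band_mean(reflectance, nir_window)
    r_red = band_mean(reflectance, red_window)
    denom = r_nir + r_red
    if denom == 0.0:
        raise ValueError("NDVI undefined: both band means are zero")
    return (r_nir - r_red) / denom


def integrate_par(irradiance: Spectrum, max_gap: float | None = None) -> float:
    """Trapezoidal integral of E(lambda) over 400-700 nm, W m^-2.

    Parameters
    ----------
    irradiance
        Downwelling spectrum; support must cover the PAR range.
    max_gap
        Largest tolerated sampling gap inside the PAR range, nm. Defaults to
        twice the median sampling step.
    """
    if irradiance.kind is not SpectrumKind.IRRADIANCE:
        raise ValueError(f"PAR requires an irradiance spectrum, got {irradiance.kind.value}")
    lo, hi = PAR_RANGE
    wl, vals = irradiance.wavelengths, irradiance.values
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"irradiance support [{wl[0]:g}, {wl[-1]:g}] nm does not cover "
            f"[{lo:g}, {hi:g}] nm"
        )
    inside = (wl >= lo) & (wl <= hi)
    grid = np.unique(np.concatenate(([lo], wl[inside], [hi])))
    steps = np.diff(grid)
    if max_gap is None:
        max_gap = 2.0 * float(np.median(np.diff(wl)))
    if np.any(steps > max_gap):
        raise ValueError(
            f"sampling gap of {steps.max():g} nm inside the PAR range "
            f"exceeds tolerance {max_gap:g} nm"
        )
    spline = CubicSpline(wl, vals)
    return float(np.trapezoid(spline(grid), grid))


def to_reflectance(s_cluster: Spectrum, s_white: Spectrum, r_white: Spectrum) -> Spectrum:
    """Reflectance factor from the in-scene white reference panel.

    R = (S_cluster / S_white) * R_white, per band, all on a shared grid.
    """
    for other, name in ((s_white, "white-panel radiance"), (r_white, "panel reflectance")):
        if not np.array_equal(s_cluster.wavelengths, other.wavelengths):
            raise ValueError(f"{name} not on the cluster radiance wavelength grid")
    nonpos = s_white.values <= 0
    if np.any(nonpos):
        band = s_white.wavelengths[nonpos][0]
        raise ValueError(f"white-panel radiance not positive at {band:g} nm")
    values = s_cluster.values / s_white.values * r_white.values
    return Spectrum(s_cluster.wavelengths, np.clip(values, 0.0, None), SpectrumKind.REFLECTANCE)


#: J s per photon-metre (h*c), for quantum conversion.
_HC = 6.62607015e-34 * 2.99792458e8
_AVOGADRO = 6.02214076e23


def par_to_quantum(irradiance: Spectrum) -> float:
    """PAR as photon flux, umol m^-2 s^-1 (not used by SIF yield)."""
    if irradiance.kind is not SpectrumKind.IRRADIANCE:
        raise ValueError("quantum PAR requires an irradiance spectrum")
    lo, hi = PAR_RANGE
    wl, vals = irradiance.wavelengths, irradiance.values
    inside = (wl >= lo) & (wl <= hi)
    wl_m = wl[inside] * 1e-9
    photon_rate = vals[inside] * wl_m / _HC  # photons m^-2 s^-1 nm^-1
    mol = np.trapezoid(photon_rate, wl[inside]) / _AVOGADRO
    return float(mol * 1e6)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    """Two-column CSV with a units header line."""
    units = {
        SpectrumKind.IRRADIANCE: "W m-2 nm-1",
        SpectrumKind.RADIANCE: "W m-2 sr-1 nm-1",
        SpectrumKind.REFLECTANCE: "unitless",
    }[s.kind]
    header = f"# kind={s.kind.value} units={units}\nwavelength_nm,value"
    np.savetxt(path, np.column_stack([s.wavelengths, s.values]),
               delimiter=",", header=header, comments="")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    kind = SpectrumKind.RADIANCE
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "kind=" in first:
        kind = SpectrumKind(first.split("kind=")[1].split()[0])
    data = np.loadtxt(path, delimiter=",", skiprows=2 if first.startswith("#") else 1)
    return Spectrum(data[:, 0], data[:, 1], kind)
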