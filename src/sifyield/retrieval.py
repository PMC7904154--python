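"""FLD / iFLD fluorescence retrieval at the O2-A band and SIF yield.

The estimator infills the 761 nm absorption trough from a band outside it
(754 nm)::

    SIF = (aR * E_out * L_in  -  E_in * L_out) / (aR * E_out - aF * E_in)

Classic FLD is the special case aR = aF = 1. The correction factors absorb
the spectral variation of reflectance (aR = r_out / r_in) and fluorescence
(aF = F_out / F_in) between the two bands; with the true factors the
retrieval is algebraically exact under the Lambertian forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .spectra import BandWindow, Spectrum, SpectrumKind

__all__ = [
    "FLDBands",
    "CorrectionFactors",
    "SIFRecord",
    "LAMBDA_IN",
    "LAMBDA_OUT",
    "fld",
    "ifld",
    "apparent_reflectance",
    "estimate_alphas",
    "bands_from_spectra",
    "sif_yield",
]

LAMBDA_IN = 761.0
LAMBDA_OUT = 754.0

#: Denominator tolerance in retrieval units.
DENOM_TOL = 1e-9


@dataclass(frozen=True)
class FLDBands:
    """Irradiance/radiance pairs at the in-line and out-of-line bands."""

    e_in: float
    e_out: float
    l_in: float
    l_out: float
    lambda_in: float = LAMBDA_IN
    lambda_out: float = LAMBDA_OUT

    def __post_init__(self) -> None:
        for name in ("e_in", "e_out", "l_in", "l_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.e_out > self.e_in:
            raise ValueError(
                f"expected E_out > E_in (continuum above trough), got "
                f"E_out={self.e_out:g}, E_in={self.e_in:g}"
            )


@dataclass(frozen=True)
class CorrectionFactors:
    alpha_r: float
    alpha_f: float

    def __post_init__(self) -> None:
        if not (self.alpha_r > 0 and np.isfinite(self.alpha_r)):
            raise ValueError("alpha_R must be positive and finite")
        if not (self.alpha_f > 0 and np.isfinite(self.alpha_f)):
            raise ValueError("alpha_F must be positive and finite")


@dataclass(frozen=True)
class SIFRecord:
    """Per-plot retrieval outcome used by the regression stage."""

    plot_id: str
    timestamp: float
    sif: float
    par: float
    ndvi: float
    fapar: float
    apar: float
    sif_yield: float
    group: str = ""


def fld(b: FLDBands) -> float:
    """Classic FLD: (E_out*L_in - E_in*L_out) / (E_out - E_in)."""
    denom = b.e_out - b.e_in
    if abs(denom) < DENOM_TOL:
        raise ValueError(
            f"no absorption contrast: E_out - E_in = {denom:g} below tolerance"
        )
    return (b.e_out * b.l_in - b.e_in * b.l_out) / denom


def ifld(b: FLDBands, cf: CorrectionFactors) -> float:
    """Improved FLD with reflectance/fluorescence correction factors."""
    denom = cf.alpha_r * b.e_out - cf.alpha_f * b.e_in
    if abs(denom) < DENOM_TOL:
        raise ValueError(f"iFLD denominator {denom:g} below tolerance {DENOM_TOL:g}")
    return (cf.alpha_r * b.e_out * b.l_in - b.e_in * b.l_out) / denom


def apparent_reflectance(radiance: Spectrum, irradiance: Spectrum) -> Spectrum:
    """pi * L / E on the camera grid (fluorescence-contaminated in the trough)."""
    if not np.array_equal(radiance.wavelengths, irradiance.wavelengths):
        raise ValueError("radiance and irradiance must share a wavelength grid")
    if np.any(irradiance.values <= 0):
        raise ValueError("irradiance must be positive at every band")
    vals = np.pi * radiance.values / irradiance.values
    return Spectrum(radiance.wavelengths, np.clip(vals, 0.0, None),
                    SpectrumKind.REFLECTANCE)


def estimate_alphas(apparent: Spectrum,
                    exclusion_window: BandWindow = BandWindow(756.0, 768.0),
                    lambda_in: float = LAMBDA_IN,
                    lambda_out: float = LAMBDA_OUT,
                    context_nm: float = 20.0,
                    fluorescence_shape: Spectrum | None = None) -> CorrectionFactors:
    """Correction factors from shoulder-band interpolation.

    The apparent reflectance inside ``exclusion_window`` (which must contain
    ``lambda_in`` but not ``lambda_out``) is replaced by a cubic-spline
    interpolant through shoulder bands within ``context_nm`` of the window;
    then ``alpha_R = R~(lambda_out) / R~(lambda_in)``. By default ``alpha_F``
    equals ``alpha_R`` (a documented simplification); passing a smooth
    ``fluorescence_shape`` switches to ``alpha_F = F(lambda_out)/F(lambda_in)``.

    Pass the *actual* band centres selected by :func:`bands_from_spectra` as
    ``lambda_in``/``lambda_out``; evaluating at the nominal 761/754 nm instead
    biases alpha_R whenever the reflectance slopes across the band.
    """
    w = exclusion_window
    if not (w.lo <= lambda_in <= w.hi):
        raise ValueError("exclusion window must contain lambda_in")
    if w.lo <= lambda_out <= w.hi:
        raise ValueError("exclusion window must not contain lambda_out")
    wl, vals = apparent.wavelengths, apparent.values
    left = (wl >= w.lo - context_nm) & (wl < w.lo)
    right = (wl > w.hi) & (wl <= w.hi + context_nm)
    if left.sum() < 2 or right.sum() < 2:
        raise ValueError(
            f"need >= 2 shoulder bands on each side of [{w.lo:g}, {w.hi:g}] nm, "
            f"got {int(left.sum())} left / {int(right.sum())} right"
        )
    shoulders = left | right
    interp = CubicSpline(wl[shoulders], vals[shoulders])
    r_in = float(interp(lambda_in))
    r_out = float(interp(lambda_out))
    if r_in <= 0 or r_out <= 0:
        raise ValueError("interpolated reflectance not positive at retrieval bands")
    alpha_r = r_out / r_in
    if fluorescence_shape is not None:
        f_in = fluorescence_shape.at(lambda_in)
        f_out = fluorescence_shape.at(lambda_out)
        if f_in <= 0 or f_out <= 0:
            raise ValueError("fluorescence shape not positive at retrieval bands")
        alpha_f = f_out / f_in
    else:
        alpha_f = alpha_r
    return CorrectionFactors(alpha_r=alpha_r, alpha_f=alpha_f)


def bands_from_spectra(radiance: Spectrum, irradiance: Spectrum,
                       lambda_in: float = LAMBDA_IN,
                       lambda_out: float = LAMBDA_OUT) -> FLDBands:
    """Pick the nearest band centres to the target wavelengths."""
    if not np.array_equal(radiance.wavelengths, irradiance.wavelengths):
        raise ValueError("radiance and irradiance must share a wavelength grid")
    i_in = radiance.index_of(lambda_in)
    i_out = radiance.index_of(lambda_out)
    if i_in == i_out:
        raise ValueError("in-line and out-of-line targets map to the same band")
    return FLDBands(
        e_in=float(irradiance.values[i_in]), e_out=float(irradiance.values[i_out]),
        l_in=float(radiance.values[i_in]), l_out=float(radiance.values[i_out]),
        lambda_in=float(radiance.wavelengths[i_in]),
        lambda_out=float(radiance.wavelengths[i_out]),
    )


def sif_yield(sif: float, par: float, ndvi: float) -> dict[str, float]:
    """fAPAR = clip(NDVI, 0, 1); APAR = PAR * fAPAR; SIFy = SIF / APAR."""
    if par <= 0:
        raise ValueError("PAR must be positive")
    fapar = float(np.clip(ndvi, 0.0, 1.0))
    apar = par * fapar
    if apar <= 0:
        raise ValueError(f"APAR is nonpositive ({apar:g}); NDVI={ndvi:g}")
    return {"fapar": fapar, "apar": apar, "sif_yield": sif / apar}
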