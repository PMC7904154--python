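"""Synthetic inputs with full ground truth.

Everything the pipeline consumes can be generated here: downwelling
irradiance with a Gaussian O2-A absorption trough at 761 nm, push-broom
scene cubes containing a white reference panel plus vegetation and soil,
per-plot fluorescence tied (negatively) to an assigned Jmax, and A/Ci
curves produced by the FvCB forward model at the standard 12 chamber
setpoints.

The radiometric convention throughout is Lambertian::

    L(lambda) = illumination * (r(lambda) * E(lambda) / pi + F(lambda))

so that apparent reflectance pi*L/E equals r whenever F == 0, and the
ratio-to-white-panel reflectance conversion is exact.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .fvcb import (
    ACiCurve,
    GmConfig,
    KineticConstants,
    PAPER_CI_SETPOINTS,
    RUBP,
    fvcb_assimilation,
    solve_assimilation_at_ci,
)
from .spectra import Spectrum, SpectrumKind, resample_spectrum

__all__ = [
    "MaterialSpec",
    "PlotTruth",
    "SceneCube",
    "TraitLink",
    "camera_grid",
    "spectrometer_grid",
    "make_irradiance",
    "leaf_reflectance",
    "soil_reflectance",
    "flat_reflectance",
    "fluorescence_spectrum",
    "default_materials",
    "default_layout",
    "make_scene",
    "make_trait_link",
    "make_aci_dataset",
    "VCMAX_RANGE",
    "JMAX_RANGE",
]

#: Observed cultivar ranges for the capacity parameters, umol m^-2 s^-1.
VCMAX_RANGE = (15.98, 318.96)
JMAX_RANGE = (118.85, 338.70)

#: 12-bit detector ceiling.
DN_MAX = 4095.0

O2A_CENTER = 761.0

WHITE_PANEL = "white_panel"
SUNLIT_LEAF = "sunlit_leaf"
SHADED_LEAF = "shaded_leaf"
SOIL = "soil"
BACKGROUND = "background"
SHADED_SOIL = "shaded_soil"


def camera_grid(n_bands: int = 240, lo: float = 400.0, hi: float = 900.0) -> np.ndarray:
    """Hyperspectral camera band centres (~2.1 nm sampling)."""
    return np.linspace(lo, hi, n_bands)


def spectrometer_grid(lo: float = 350.0, hi: float = 1000.0, step: float = 0.35) -> np.ndarray:
    """Irradiance spectrometer grid (~0.35 nm sampling)."""
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def make_irradiance(wavelength_grid: np.ndarray | None = None,
                    continuum_level: float = 1.2,
                    line_center: float = O2A_CENTER,
                    line_depth: float = 0.7,
                    line_width: float = 1.5,
                    seed: int | None = None,
                    noise_sd: float = 0.0) -> Spectrum:
    """Continuum irradiance with a Gaussian absorption trough.

    ``E(line_center) = continuum_level * (1 - line_depth)`` exactly;
    ``line_width`` is the Gaussian sigma in nm.
    """
    if line_width <= 0:
        raise ValueError("line_width must be positive")
    if not 0.0 <= line_depth < 1.0:
        raise ValueError("line_depth must lie in [0, 1)")
    wl = spectrometer_grid() if wavelength_grid is None else np.asarray(wavelength_grid, float)
    trough = line_depth * np.exp(-0.5 * ((wl - line_center) / line_width) ** 2)
    values = continuum_level * (1.0 - trough)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, wl.size), 0.0, None)
    return Spectrum(wl, values, SpectrumKind.IRRADIANCE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def leaf_reflectance(wavelength_grid: np.ndarray,
                     r_red: float = 0.05,
                     r_nir: float = 0.50,
                     edge_center: float = 715.0,
                     edge_width: float = 12.0,
                     tilt_per_nm: float = 0.0) -> Spectrum:
    """Logistic red-edge template for vegetation.

    ``tilt_per_nm`` applies a multiplicative slope anchored at 761 nm so the
    reflectance ratio across the retrieval bands can be controlled:
    r(754)/r(761) = (1 + tilt*(754-761)) / 1.
    """
    wl = np.asarray(wavelength_grid, float)
    r = r_red + (r_nir - r_red) * _sigmoid((wl - edge_center) / edge_width)
    if tilt_per_nm != 0.0:
        r = r * (1.0 + tilt_per_nm * (wl - O2A_CENTER))
    return Spectrum(wl, np.clip(r, 0.0, 1.0), SpectrumKind.REFLECTANCE)


def soil_reflectance(wavelength_grid: np.ndarray, level: float = 0.20,
                     slope_per_nm: float = 4e-5) -> Spectrum:
    """Bright, gently sloping soil (NDVI ~ 0.05 or less)."""
    wl = np.asarray(wavelength_grid, float)
    r = level + slope_per_nm * (wl - 650.0)
    return Spectrum(wl, np.clip(r, 0.0, 1.0), SpectrumKind.REFLECTANCE)


def flat_reflectance(wavelength_grid: np.ndarray, level: float) -> Spectrum:
    wl = np.asarray(wavelength_grid, float)
    return Spectrum(wl, np.full(wl.size, float(level)), SpectrumKind.REFLECTANCE)


def fluorescence_spectrum(wavelength_grid: np.ndarray, phi_f: float,
                          peak: float = 740.0, sigma: float = 35.0,
                          scale: float = 0.1) -> Spectrum:
    """Single-Gaussian fluorescence radiance, ``phi_f * scale`` at the peak.

    Units W m^-2 sr^-1 nm^-1; only the values near 754-761 nm matter to the
    retrieval, so the shape is a configurable stand-in.
    """
    if phi_f < 0:
        raise ValueError("fluorescence yield must be nonnegative")
    wl = np.asarray(wavelength_grid, float)
    f = phi_f * scale * np.exp(-0.5 * ((wl - peak) / sigma) ** 2)
    return Spectrum(wl, f, SpectrumKind.RADIANCE)


@dataclass(frozen=True)
class MaterialSpec:
    """One scene material: reflectance, fluorescence and an illumination dimming."""

    name: str
    reflectance_spectrum: Spectrum
    fluorescence_spectrum: Spectrum
    illumination_factor: float = 1.0

    def __post_init__(self) -> None:
        r = self.reflectance_spectrum
        f = self.fluorescence_spectrum
        if np.any(r.values < 0) or np.any(r.values > 1):
            raise ValueError(f"{self.name}: reflectance outside [0, 1]")
        if np.any(f.values < 0):
            raise ValueError(f"{self.name}: negative fluorescence")
        if not 0.0 < self.illumination_factor <= 1.0:
            raise ValueError(f"{self.name}: illumination_factor outside (0, 1]")
        if self.name == WHITE_PANEL:
            if np.any(f.values != 0):
                raise ValueError("white panel must have zero fluorescence")
            if np.ptp(r.values) > 1e-12:
                raise ValueError("white panel reflectance must be flat")


@dataclass(frozen=True)
class PlotTruth:
    """Ground truth for one plot: capacity parameters, yield and grouping."""

    plot_id: str
    vcmax_true: float
    jmax_true: float
    rd_true: float
    phi_f: float
    group: str
    date: _dt.date

    def __post_init__(self) -> None:
        if not VCMAX_RANGE[0] <= self.vcmax_true <= VCMAX_RANGE[1]:
            raise ValueError(f"Vcmax {self.vcmax_true:g} outside {VCMAX_RANGE}")
        if not JMAX_RANGE[0] <= self.jmax_true <= JMAX_RANGE[1]:
            raise ValueError(f"Jmax {self.jmax_true:g} outside {JMAX_RANGE}")
        if self.rd_true <= 0:
            raise ValueError("Rd must be positive")
        if self.phi_f < 0:
            raise ValueError("fluorescence yield must be nonnegative")


@dataclass
class SceneCube:
    """Encoded push-broom cube plus the generator's ground truth."""

    dn: np.ndarray                      # (rows, cols, bands), float, clipped to 12 bit
    wavelengths: np.ndarray             # band centres, nm
    gain: np.ndarray                    # per band
    offset: np.ndarray                  # per band
    labels: np.ndarray                  # (rows, cols) material index
    material_names: list[str]
    true_sif: dict[str, float]          # material -> illuminated F at 761 nm
    saturated: np.ndarray               # (rows, cols) any-band saturation flag

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dn.shape


def default_materials(wavelength_grid: np.ndarray,
                      phi_f: float = 0.03,
                      ndvi_target: float | None = None,
                      r_white: float = 0.99,
                      leaf_tilt_per_nm: float = 0.0,
                      shade_factor: float = 0.4,
                      fluor_kwargs: dict | None = None) -> list[MaterialSpec]:
    """The six-material scene content used throughout the tests.

    If ``ndvi_target`` is given, the leaf red reflectance is chosen so the
    analytic NDVI of the leaf template equals the target (NIR plateau fixed).
    """
    wl = np.asarray(wavelength_grid, float)
    r_nir = 0.50
    if ndvi_target is not None:
        if not 0.0 < ndvi_target < 1.0:
            raise ValueError("ndvi_target must be in (0, 1)")
        r_red = r_nir * (1.0 - ndvi_target) / (1.0 + ndvi_target)
    else:
        r_red = 0.05
    fluor = fluorescence_spectrum(wl, phi_f, **(fluor_kwargs or {}))
    no_fluor = Spectrum(wl, np.zeros(wl.size), SpectrumKind.RADIANCE)
    leaf = leaf_reflectance(wl, r_red=r_red, r_nir=r_nir, tilt_per_nm=leaf_tilt_per_nm)
    return [
        MaterialSpec(WHITE_PANEL, flat_reflectance(wl, r_white), no_fluor, 1.0),
        MaterialSpec(SUNLIT_LEAF, leaf, fluor, 1.0),
        MaterialSpec(SHADED_LEAF, leaf, fluor, shade_factor),
        MaterialSpec(SOIL, soil_reflectance(wl), no_fluor, 1.0),
        MaterialSpec(SHADED_SOIL, soil_reflectance(wl), no_fluor, 0.5),
        MaterialSpec(BACKGROUND, flat_reflectance(wl, 0.02), no_fluor, 1.0),
    ]


def default_layout(n_rows: int = 48, n_cols: int = 640,
                   material_names: list[str] | None = None) -> np.ndarray:
    """Label image for the six default materials.

    The white panel sits near-nadir (centre columns) as it would in the
    camera's field of view; sunlit leaves occupy a broad central block so
    the +-15 degree mask keeps plenty of them.
    """
    names = material_names or [WHITE_PANEL, SUNLIT_LEAF, SHADED_LEAF, SOIL,
                               SHADED_SOIL, BACKGROUND]
    idx = {n: i for i, n in enumerate(names)}
    lay = np.full((n_rows, n_cols), idx[BACKGROUND], dtype=int)
    r1 = max(2, n_rows // 6)
    c_lo, c_hi = int(n_cols * 0.40), int(n_cols * 0.60)
    lay[:r1, c_lo:c_hi] = idx[WHITE_PANEL]
    lay[r1:, : int(n_cols * 0.15)] = idx[SOIL]
    lay[r1:, int(n_cols * 0.15): int(n_cols * 0.25)] = idx[SHADED_SOIL]
    lay[r1:, int(n_cols * 0.25): int(n_cols * 0.62)] = idx[SUNLIT_LEAF]
    lay[r1:, int(n_cols * 0.62): int(n_cols * 0.85)] = idx[SHADED_LEAF]
    return lay


def make_scene(materials: list[MaterialSpec],
               layout: np.ndarray,
               irradiance: Spectrum,
               gain: np.ndarray | float | None = None,
               offset: np.ndarray | float = 0.0,
               noise_sd: float = 0.0,
               seed: int | None = None,
               wavelengths: np.ndarray | None = None) -> SceneCube:
    """Render materials to an encoded DN cube under the forward model.

    DN = (L - offset) / gain + N(0, noise_sd), clipped to [0, 4095]. When
    ``gain`` is None it is set from the white panel so its peak radiance
    encodes ~15% below saturation (mirroring integration-time setting).
    """
    names = [m.name for m in materials]
    if WHITE_PANEL not in names:
        raise ValueError("layout must contain a white-panel region for Eq-1-style "
                         "reflectance conversion")
    layout = np.asarray(layout)
    if layout.ndim != 2:
        raise ValueError("layout must be a 2-D label image")
    if layout.min() < 0 or layout.max() >= len(materials):
        raise ValueError("layout labels outside the material list")
    if WHITE_PANEL in names and not np.any(layout == names.index(WHITE_PANEL)):
        raise ValueError("layout must contain at least one white-panel pixel")

    wl = np.asarray(wavelengths, float) if wavelengths is not None else camera_grid()
    e_cam = resample_spectrum(irradiance, wl) if not np.array_equal(
        irradiance.wavelengths, wl) else irradiance

    # Per-material radiance on the camera grid.
    radiances = np.empty((len(materials), wl.size))
    true_sif: dict[str, float] = {}
    i761 = int(np.argmin(np.abs(wl - O2A_CENTER)))
    for i, m in enumerate(materials):
        r = m.reflectance_spectrum
        f = m.fluorescence_spectrum
        if not np.array_equal(r.wavelengths, wl):
            r = resample_spectrum(r, wl)
        if not np.array_equal(f.wavelengths, wl):
            f = resample_spectrum(f, wl)
        radiances[i] = m.illumination_factor * (r.values * e_cam.values / np.pi + f.values)
        true_sif[m.name] = float(m.illumination_factor * f.values[i761])

    gain_arr, offset_arr = _resolve_encoding(gain, offset, radiances, wl.size)
    cube_l = radiances[layout]                     # (rows, cols, bands)
    dn = (cube_l - offset_arr) / gain_arr
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dn = dn + rng.normal(0.0, noise_sd, dn.shape)
    saturated = np.any(dn >= DN_MAX, axis=2) | np.any(dn < 0, axis=2)
    dn = np.clip(dn, 0.0, DN_MAX)
    return SceneCube(dn=dn, wavelengths=wl, gain=gain_arr, offset=offset_arr,
                     labels=layout.copy(), material_names=names,
                     true_sif=true_sif, saturated=saturated)


def _resolve_encoding(gain, offset, radiances, n_bands):
    if gain is None:
        peak = float(radiances.max())
        gain = peak / (0.85 * DN_MAX)
    gain_arr = np.broadcast_to(np.asarray(gain, float), (n_bands,)).copy()
    if np.any(gain_arr <= 0):
        raise ValueError("gain must be positive at every band")
    offset_arr = np.broadcast_to(np.asarray(offset, float), (n_bands,)).copy()
    return gain_arr, offset_arr


@dataclass(frozen=True)
class TraitLink:
    """Generated per-plot optical traits plus the generating link strengths."""

    fluorescence: dict[str, Spectrum]       # plot_id -> F(lambda)
    ndvi_targets: dict[str, float]          # plot_id -> canopy NDVI
    phi_f: dict[str, float]
    generating_r2_phif: float               # R2 of phiF ~ Jmax in the sample
    generating_r2_apar: float               # R2 of NDVI target ~ Vcmax


def make_trait_link(truth: list[PlotTruth],
                    apar_model: tuple[float, float] = (0.0018, 0.25),
                    phif_model: tuple[float, float] = (-1.0e-4, 0.065),
                    phif_noise_sd: float = 0.0,
                    ndvi_noise_sd: float = 0.0,
                    wavelength_grid: np.ndarray | None = None,
                    seed: int | None = None,
                    fluor_kwargs: dict | None = None) -> TraitLink:
    """Tie per-plot fluorescence yield (negatively) to Jmax and NDVI to Vcmax.

    ``phif_model = (slope, intercept)`` with slope < 0 encodes the hypothesis
    under test; ``apar_model`` links the NDVI target to Vcmax so higher
    capacity co-occurs with more light capture. The realised sample R2 of
    both links is returned for comparison with pipeline-recovered values.
    """
    slope_a, inter_a = apar_model
    slope_p, inter_p = phif_model
    rng = np.random.default_rng(seed)
    wl = spectrometer_grid() if wavelength_grid is None else np.asarray(wavelength_grid, float)

    jmax = np.array([t.jmax_true for t in truth])
    vcmax = np.array([t.vcmax_true for t in truth])
    phi_mean = inter_p + slope_p * jmax
    if np.any(phi_mean <= 0):
        raise ValueError("phiF model yields nonpositive fluorescence yield; "
                         "raise the intercept or flatten the slope")
    phi = phi_mean + (rng.normal(0.0, phif_noise_sd, jmax.size) if phif_noise_sd > 0 else 0.0)
    phi = np.clip(phi, 1e-5, None)
    ndvi_t = inter_a + slope_a * vcmax
    ndvi_t = ndvi_t + (rng.normal(0.0, ndvi_noise_sd, vcmax.size) if ndvi_noise_sd > 0 else 0.0)
    ndvi_t = np.clip(ndvi_t, 0.15, 0.95)

    fluor = {t.plot_id: fluorescence_spectrum(wl, float(p), **(fluor_kwargs or {}))
             for t, p in zip(truth, phi)}
    return TraitLink(
        fluorescence=fluor,
        ndvi_targets={t.plot_id: float(n) for t, n in zip(truth, ndvi_t)},
        phi_f={t.plot_id: float(p) for t, p in zip(truth, phi)},
        generating_r2_phif=_sample_r2(jmax, phi),
        generating_r2_apar=_sample_r2(vcmax, ndvi_t),
    )


def _sample_r2(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def make_aci_dataset(truth: list[PlotTruth],
                     ci_setpoints=PAPER_CI_SETPOINTS,
                     constants: KineticConstants = KineticConstants(),
                     gm_config: GmConfig = GmConfig(),
                     noise_sd: float = 0.3,
                     leaves_per_plot: int = 3,
                     leaf_jitter_frac: float = 0.0,
                     leaf_temperature: float = 25.0,
                     seed: int | None = None) -> tuple[list[ACiCurve], dict[str, bool]]:
    """FvCB-forward A/Ci curves for each plot's leaves.

    Returns the curves plus a per-plot flag that is True when the true
    parameters leave no RuBP-limited setpoint (the double-Rubisco-knockdown
    situation, where Jmax cannot be identified).
    """
    ci = np.asarray(ci_setpoints, float)
    if np.any(ci <= 0):
        raise ValueError("Ci setpoints must be positive")
    rng = np.random.default_rng(seed)
    kt = constants.at_leaf_temperature(leaf_temperature)
    gm = gm_config.at(leaf_temperature)
    curves: list[ACiCurve] = []
    no_rubp: dict[str, bool] = {}
    for t in truth:
        a_true = np.array([solve_assimilation_at_ci(c, t.vcmax_true, t.jmax_true,
                                                    t.rd_true, gm, kt) for c in ci])
        cc = ci - a_true / gm
        _, labels = fvcb_assimilation(cc, t.vcmax_true, t.jmax_true, t.rd_true, kt)
        no_rubp[t.plot_id] = not bool(np.any(labels == RUBP))
        for leaf in range(leaves_per_plot):
            if leaf_jitter_frac > 0:
                jit = rng.normal(1.0, leaf_jitter_frac, 3)
                v, j, r = (t.vcmax_true * jit[0], t.jmax_true * jit[1],
                           t.rd_true * max(jit[2], 0.1))
                a_leaf = np.array([solve_assimilation_at_ci(c, v, j, r, gm, kt)
                                   for c in ci])
            else:
                a_leaf = a_true
            noise = rng.normal(0.0, noise_sd, ci.size) if noise_sd > 0 else 0.0
            curves.append(ACiCurve(plot_id=t.plot_id, leaf_id=f"leaf{leaf + 1}",
                                   ci=ci.copy(), a=a_leaf + noise,
                                   leaf_temperature=leaf_temperature))
    return curves, no_rubp
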