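"""DN-to-radiance calibration, k-means segmentation and plot aggregation.

The processing chain mirrors a push-broom canopy acquisition: calibrate the
raw cube, cluster per-pixel radiance spectra (k = 6), take the brightest
cluster as the white reference panel, split the NDVI > 0.1 clusters into
sunlit and shaded foliage by mean radiance, and average sunlit-leaf spectra
inside the near-nadir scan-angle mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .spectra import BandWindow, Spectrum, SpectrumKind, ndvi, to_reflectance

__all__ = [
    "ClusterMap",
    "AngleMask",
    "calibrate_dn",
    "cluster_image",
    "identify_white_panel",
    "identify_sunlit_leaves",
    "angle_mask",
    "plot_mean_spectra",
]

DN_MAX = 4095.0
DEFAULT_K = 6
NDVI_THRESHOLD = 0.1


@dataclass
class ClusterMap:
    """Per-pixel k-means labels with per-cluster summaries."""

    labels: np.ndarray                 # (rows, cols), 0..k-1
    k: int
    mean_radiance: np.ndarray          # (k,) mean over member pixels and bands
    mean_spectra: list[Spectrum]       # per-cluster mean radiance spectrum
    valid: np.ndarray                  # (rows, cols) pixels used for stats

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels outside 0..k-1")
        if not np.all(np.isfinite(self.mean_radiance)):
            raise ValueError("non-finite cluster means")


@dataclass(frozen=True)
class AngleMask:
    """Cross-track scan-angle mask for a push-broom line of spatial channels."""

    n_channels: int
    half_fov: float
    keep_half_angle: float
    kept_columns: np.ndarray

    def column_angles(self) -> np.ndarray:
        return _column_angles(self.n_channels, self.half_fov)


def calibrate_dn(cube_dn: np.ndarray, gain: np.ndarray, offset: np.ndarray,
                 dn_max: float = DN_MAX) -> tuple[np.ndarray, np.ndarray]:
    """L = gain * DN + offset per band; returns (radiance, saturated_mask).

    Saturated pixels (any band at the maximum code) are flagged, never
    silently used downstream.
    """
    gain = np.asarray(gain, float)
    offset = np.asarray(offset, float)
    if np.any(gain <= 0):
        raise ValueError("gain must be positive at every band")
    cube_dn = np.asarray(cube_dn, float)
    radiance = gain * cube_dn + offset
    saturated = np.any(cube_dn >= dn_max, axis=-1)
    return radiance, saturated


def cluster_image(radiance_cube: np.ndarray, k: int = DEFAULT_K,
                  seed: int | None = 0, restarts: int = 3,
                  exclude: np.ndarray | None = None,
                  wavelengths: np.ndarray | None = None) -> ClusterMap:
    """K-means on per-pixel radiance spectra (Euclidean, no normalisation).

    ``exclude`` marks pixels (e.g. saturated ones) left out of both fitting
    and the cluster summaries; they still receive a nearest-centroid label.
    """
    rows, cols, bands = radiance_cube.shape
    flat = radiance_cube.reshape(-1, bands)
    valid = np.ones(rows * cols, dtype=bool)
    if exclude is not None:
        valid &= ~exclude.reshape(-1)
    n_fit = int(valid.sum())
    if n_fit < k:
        raise ValueError(f"{n_fit} usable pixels < k={k}")
    if np.unique(flat[valid], axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct pixel spectra")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(flat[valid])
    labels = km.predict(flat).reshape(rows, cols)

    mean_radiance = np.empty(k)
    mean_spectra: list[Spectrum] = []
    valid2d = valid.reshape(rows, cols)
    if wavelengths is None:
        wavelengths = np.arange(bands, dtype=float)  # band indices as a stand-in
    wavelengths = np.asarray(wavelengths, float)
    for c in range(k):
        member = (labels == c) & valid2d
        if not np.any(member):
            member = labels == c  # degenerate: all members excluded
        spec = radiance_cube[member].mean(axis=0)
        mean_radiance[c] = float(spec.mean())
        mean_spectra.append(Spectrum(wavelengths, spec, SpectrumKind.RADIANCE))
    return ClusterMap(labels=labels, k=k, mean_radiance=mean_radiance,
                      mean_spectra=mean_spectra, valid=valid2d)


def identify_white_panel(cm: ClusterMap, tie_rtol: float = 1e-6) -> int:
    """Brightest cluster by mean radiance = the white reference panel."""
    if cm.k < 2:
        raise ValueError("need at least 2 clusters")
    order = np.argsort(cm.mean_radiance)[::-1]
    top, second = cm.mean_radiance[order[0]], cm.mean_radiance[order[1]]
    if top > 0 and (top - second) / top < tie_rtol:
        raise ValueError(
            f"white-panel identification is a tie (means {top:g} vs {second:g}); "
            "manual disambiguation required"
        )
    return int(order[0])


def identify_sunlit_leaves(cm: ClusterMap, white_id: int, r_white: Spectrum,
                           ndvi_threshold: float = NDVI_THRESHOLD,
                           require_two: bool = True) -> tuple[int, dict[int, float]]:
    """Among NDVI > threshold clusters, the brighter one is sunlit foliage.

    Cluster reflectance comes from the ratio to the white-panel cluster mean.
    Returns the sunlit cluster id and the per-cluster NDVI values actually
    computed (white panel excluded).
    """
    white_spec = cm.mean_spectra[white_id]
    ndvi_by_cluster: dict[int, float] = {}
    for c in range(cm.k):
        if c == white_id:
            continue
        refl = to_reflectance(cm.mean_spectra[c], white_spec, r_white)
        ndvi_by_cluster[c] = ndvi(refl)
    veg = [c for c, v in ndvi_by_cluster.items() if v > ndvi_threshold]
    if not veg:
        raise ValueError(f"no cluster exceeds NDVI threshold {ndvi_threshold:g}")
    if require_two and len(veg) != 2:
        if len(veg) == 1:
            import warnings
            warnings.warn("only one vegetation cluster found; returning it",
                          stacklevel=2)
            return veg[0], ndvi_by_cluster
        raise ValueError(
            f"expected exactly 2 vegetation clusters, found {len(veg)}; "
            "pass require_two=False to take the brightest"
        )
    sunlit = max(veg, key=lambda c: cm.mean_radiance[c])
    return int(sunlit), ndvi_by_cluster


def _column_angles(n_channels: int, half_fov: float) -> np.ndarray:
    # linspace keeps the endpoints exact (the arange form drifts by ~1 ulp)
    return np.linspace(-half_fov, half_fov, n_channels)


def angle_mask(n_channels: int = 640, half_fov: float = 46.1,
               keep_half_angle: float = 15.0) -> AngleMask:
    """Columns whose view angle satisfies |angle| <= keep_half_angle.

    Column i (0-based) maps linearly to -half_fov + i * 2*half_fov/(n-1).
    """
    if keep_half_angle > half_fov:
        raise ValueError("keep_half_angle must not exceed half_fov")
    if keep_half_angle < 0:
        raise ValueError("keep_half_angle must be nonnegative")
    angles = _column_angles(n_channels, half_fov)
    kept = np.nonzero(np.abs(angles) <= keep_half_angle)[0]
    if kept.size == 0:
        raise ValueError("mask keeps no columns")
    return AngleMask(n_channels=n_channels, half_fov=half_fov,
                     keep_half_angle=keep_half_angle, kept_columns=kept)


def plot_mean_spectra(radiance_cube: np.ndarray, wavelengths: np.ndarray,
                      cm: ClusterMap, sunlit_id: int, mask: AngleMask,
                      white_id: int, r_white: Spectrum
                      ) -> tuple[Spectrum, Spectrum, float]:
    """Masked sunlit-pixel means: (radiance, reflectance, NDVI of the mean)."""
    rows, cols, bands = radiance_cube.shape
    if mask.n_channels != cols:
        raise ValueError(f"mask built for {mask.n_channels} channels, cube has {cols}")
    col_keep = np.zeros(cols, dtype=bool)
    col_keep[mask.kept_columns] = True
    select = (cm.labels == sunlit_id) & cm.valid & col_keep[None, :]
    if not np.any(select):
        raise ValueError("no sunlit pixels inside the angle mask")
    wavelengths = np.asarray(wavelengths, float)
    mean_rad = Spectrum(wavelengths, radiance_cube[select].mean(axis=0),
                        SpectrumKind.RADIANCE)
    white_spec = Spectrum(wavelengths, cm.mean_spectra[white_id].values,
                          SpectrumKind.RADIANCE)
    mean_refl = to_reflectance(mean_rad, white_spec, r_white)
    return mean_rad, mean_refl, ndvi(mean_refl)
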