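"""Snow/ice masking via NDSI and a near-infrared water screen.

A pixel counts as snow/ice when its normalized difference snow index
NDSI = (green - SWIR) / (green + SWIR) exceeds 0.4 *and* its NIR
reflectance exceeds 0.11 (the NIR test removes open water, which is
dark in the near infrared but can show a high NDSI). Both inequalities
are strict; pixels sitting exactly on a threshold are excluded. Nodata
in any contributing band excludes the pixel, a conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ParameterError
from .reflectance import ensure_reflectance
from .scene import SceneBundle

#: Default NDSI threshold for snow detection.
NDSI_THRESHOLD = 0.4
#: Default NIR reflectance threshold masking out water.
NIR_THRESHOLD = 0.11


def ndsi(green: np.ndarray, swir: np.ndarray) -> np.ndarray:
    """Normalized difference snow index, (green - SWIR)/(green + SWIR).

    Pixels where green + SWIR <= 0 (or either band is non-finite) are
    NaN. Valid values lie in [-1, 1] for nonnegative reflectances.
    """
    green = np.asarray(green, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if green.shape != swir.shape:
        raise DimensionError(
            f"green {green.shape} and swir {swir.shape} grids differ in shape"
        )
    total = green + swir
    invalid = ~np.isfinite(total) | (total <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(invalid, np.nan, (green - swir) / np.where(invalid, 1.0, total))
    return out


@dataclass
class SnowMask:
    """Boolean snow/ice grid with the thresholds that produced it."""

    mask: np.ndarray
    ndsi_threshold: float = NDSI_THRESHOLD
    nir_threshold: float = NIR_THRESHOLD

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_snow_pixels(self) -> int:
        return int(self.mask.sum())


def make_snow_mask(
    ndsi_grid: np.ndarray,
    nir_grid: np.ndarray,
    ndsi_threshold: float = NDSI_THRESHOLD,
    nir_threshold: float = NIR_THRESHOLD,
) -> SnowMask:
    """Snow mask: NDSI > ndsi_threshold AND NIR > nir_threshold, strictly.

    NaN compares false in both tests, so nodata pixels are never snow.
    """
    ndsi_grid = np.asarray(ndsi_grid, dtype=float)
    nir_grid = np.asarray(nir_grid, dtype=float)
    if ndsi_grid.shape != nir_grid.shape:
        raise DimensionError("NDSI and NIR grids differ in shape")
    with np.errstate(invalid="ignore"):
        mask = (ndsi_grid > ndsi_threshold) & (nir_grid > nir_threshold)
    return SnowMask(mask=mask, ndsi_threshold=ndsi_threshold, nir_threshold=nir_threshold)


def scene_snow_mask(
    bundle: SceneBundle,
    ndsi_threshold: float = NDSI_THRESHOLD,
    nir_threshold: float = NIR_THRESHOLD,
) -> SnowMask:
    """Snow mask for a scene, converting DN to reflectance if needed."""
    refl = ensure_reflectance(bundle)
    nodata = refl.nodata_mask()
    ndsi_grid = ndsi(refl.bands["green"], refl.bands["swir"])
    nir = np.where(nodata, np.nan, refl.bands["nir"])
    ndsi_grid = np.where(nodata, np.nan, ndsi_grid)
    return make_snow_mask(ndsi_grid, nir, ndsi_threshold, nir_threshold)


def snow_area(mask: SnowMask, pixel_size_m: float) -> float:
    """Total snow-covered area in m^2: snow pixel count x pixel area."""
    if not pixel_size_m > 0:
        raise ParameterError("pixel_size_m must be positive")
    return mask.n_snow_pixels * pixel_size_m * pixel_size_m
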