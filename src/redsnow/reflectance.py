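"""DN-to-reflectance conversion and the red:green band-ratio map.

Raw Landsat-style digital numbers are first rescaled to at-sensor
radiance ``L = gain * DN + bias`` and then to top-of-atmosphere (TOA)
reflectance

    rho = pi * L * d^2 / (ESUN * cos(theta_s)),

where ``d`` is the earth-sun distance in astronomical units, ``ESUN``
the band's mean exoatmospheric irradiance and ``theta_s`` the solar
zenith angle (90 deg minus the scene sun elevation). Reflectance is not
clamped to [0, 1]: bright snow can legitimately exceed 1 and clamping
would bias the band ratio.

Red snow is detected from the per-pixel ratio of red-band to green-band
reflectance; ratios above 1.0 indicate red snow while white snow and
ice reflect more strongly in the green band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError, UnitsError
from .scene import BAND_ROLES, UNITS_DN, UNITS_REFLECTANCE, SceneBundle


def earth_sun_distance(doy: int | np.ndarray) -> float | np.ndarray:
    """Earth-sun distance in AU from day of year.

    Uses the standard cosine approximation
    ``d = 1 - 0.01672 * cos(0.9856 deg * (doy - 4))``; the error versus
    an ephemeris is below 0.1%, well under the radiometric noise floor.
    """
    doy_arr = np.asarray(doy)
    if np.any(doy_arr < 1) or np.any(doy_arr > 366):
        raise ParameterError("day of year must be in [1, 366]")
    d = 1.0 - 0.01672 * np.cos(np.radians(0.9856 * (doy_arr - 4)))
    return float(d) if np.isscalar(doy) else d


def toa_reflectance(
    dn_grid: np.ndarray,
    gain: float,
    bias: float,
    esun: float,
    doy: int,
    sun_elevation_deg: float,
    nodata_value: float | None = None,
) -> np.ndarray:
    """Convert one band of digital numbers to TOA reflectance.

    Nodata pixels (equal to ``nodata_value`` or non-finite) propagate
    as NaN. The transform is affine in DN for fixed metadata.
    """
    if not gain > 0:
        raise ParameterError("gain must be positive")
    if not (0.0 < sun_elevation_deg <= 90.0):
        raise ParameterError("sun_elevation_deg must be in (0, 90]")
    dn = np.asarray(dn_grid, dtype=float)
    invalid = ~np.isfinite(dn)
    if nodata_value is not None:
        invalid |= dn == nodata_value
    d = earth_sun_distance(doy)
    radiance = gain * dn + bias
    cos_zenith = math.cos(math.radians(90.0 - sun_elevation_deg))
    rho = math.pi * radiance * d * d / (esun * cos_zenith)
    rho = np.where(invalid, np.nan, rho)
    return rho


def bundle_to_reflectance(bundle: SceneBundle) -> SceneBundle:
    """Convert every band of a DN bundle to TOA reflectance.

    Raises :class:`UnitsError` if the bundle is already in reflectance
    units, and :class:`ParameterError` if radiometric metadata is
    missing.
    """
    if bundle.units == UNITS_REFLECTANCE:
        raise UnitsError("bundle is already in reflectance units")
    if bundle.gain is None or bundle.bias is None or bundle.esun is None:
        raise ParameterError("DN bundle lacks gain/bias/ESUN metadata")
    bands = {
        role: toa_reflectance(
            bundle.bands[role],
            gain=bundle.gain[role],
            bias=bundle.bias[role],
            esun=bundle.esun[role],
            doy=bundle.acquisition_doy,
            sun_elevation_deg=bundle.sun_elevation_deg,
            nodata_value=bundle.nodata_value,
        )
        for role in BAND_ROLES
    }
    return bundle.with_bands(bands, UNITS_REFLECTANCE)


def ensure_reflectance(bundle: SceneBundle) -> SceneBundle:
    """Return the bundle in reflectance units, converting from DN if needed."""
    if bundle.units == UNITS_REFLECTANCE:
        return bundle
    return bundle_to_reflectance(bundle)


@dataclass
class RatioMap:
    """Per-pixel red:green reflectance ratio with an explicit nodata mask."""

    values: np.ndarray
    nodata: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.values.shape != self.nodata.shape:
            raise DimensionError("ratio values and nodata mask differ in shape")


def band_ratio(
    red: np.ndarray,
    green: np.ndarray,
    nodata_value: float | None = None,
) -> RatioMap:
    """Elementwise red/green reflectance ratio.

    Pixels where the green reflectance is non-positive, or where either
    band is nodata/non-finite, are flagged nodata rather than raising.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise DimensionError(
            f"red {red.shape} and green {green.shape} grids differ in shape"
        )
    invalid = ~np.isfinite(red) | ~np.isfinite(green)
    if nodata_value is not None:
        invalid |= (red == nodata_value) | (green == nodata_value)
    invalid |= green <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(invalid, np.nan, red / np.where(invalid, 1.0, green))
    return RatioMap(values=values, nodata=invalid)


def scene_band_ratio(bundle: SceneBundle) -> RatioMap:
    """Red:green ratio map for a scene, converting DN to reflectance first."""
    refl = ensure_reflectance(bundle)
    return band_ratio(
        refl.bands["red"], refl.bands["green"], nodata_value=refl.nodata_value
    )
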