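"""Scene container and raster/sidecar I/O.

A *scene* is one satellite acquisition: four co-registered band grids
(green 520-600 nm, red 630-690 nm, near-infrared, shortwave-infrared)
plus the radiometric and solar metadata needed to convert raw digital
numbers (DN) to top-of-atmosphere reflectance.

On disk a scene is a 4-band float TIFF (band order green, red, NIR,
SWIR) with a flat ``key=value`` sidecar text file carrying per-band
gain/bias/ESUN, sun elevation, day of year, pixel size, nodata value
and a units flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import DimensionError, ParameterError

#: Band roles in canonical storage order.
BAND_ROLES = ("green", "red", "nir", "swir")

#: Units flags for :attr:`SceneBundle.units`.
UNITS_DN = "dn"
UNITS_REFLECTANCE = "reflectance"


@dataclass
class SceneBundle:
    """Multiband grid plus radiometric/solar metadata for one acquisition.

    Parameters
    ----------
    bands
        Mapping of band role (``green``/``red``/``nir``/``swir``) to a 2-D
        float array, all of identical shape.
    units
        ``"dn"`` for raw digital numbers, ``"reflectance"`` for
        top-of-atmosphere reflectance.
    gain, bias
        Per-band radiometric rescaling (radiance per DN, radiance offset);
        required to convert DN bundles, optional for reflectance bundles.
    esun
        Per-band mean exoatmospheric solar irradiance (W m^-2 um^-1).
    sun_elevation_deg
        Scene-level solar elevation above the horizon, in (0, 90].
    acquisition_doy
        Day of year of acquisition, 1-366.
    pixel_size_m
        Ground pixel edge length in meters.
    nodata_value
        Raster fill value marking invalid pixels, or ``None``.
    year
        Optional acquisition year, used by the time-series report.
    """

    bands: dict[str, np.ndarray]
    units: str
    sun_elevation_deg: float
    acquisition_doy: int
    pixel_size_m: float
    gain: dict[str, float] | None = None
    bias: dict[str, float] | None = None
    esun: dict[str, float] | None = None
    nodata_value: float | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        missing = [r for r in BAND_ROLES if r not in self.bands]
        if missing:
            raise ParameterError(f"scene is missing band roles: {missing}")
        shapes = {r: np.asarray(g).shape for r, g in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise DimensionError(f"band grids differ in shape: {shapes}")
        if self.units not in (UNITS_DN, UNITS_REFLECTANCE):
            raise ParameterError(f"unknown units flag {self.units!r}")
        if not (0.0 < self.sun_elevation_deg <= 90.0):
            raise ParameterError("sun_elevation_deg must be in (0, 90]")
        if not (1 <= int(self.acquisition_doy) <= 366):
            raise ParameterError("acquisition_doy must be in [1, 366]")
        if not self.pixel_size_m > 0:
            raise ParameterError("pixel_size_m must be positive")
        self.bands = {r: np.asarray(self.bands[r], dtype=float) for r in BAND_ROLES}

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["green"].shape

    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, true where any band equals the nodata value or is NaN."""
        mask = np.zeros(self.shape, dtype=bool)
        for grid in self.bands.values():
            mask |= ~np.isfinite(grid)
            if self.nodata_value is not None:
                mask |= grid == self.nodata_value
        return mask

    def with_bands(self, bands: dict[str, np.ndarray], units: str) -> "SceneBundle":
        return replace(self, bands=dict(bands), units=units)


def _sidecar_path(raster_path: Path) -> Path:
    return raster_path.with_suffix(raster_path.suffix + ".meta")


def write_scene(bundle: SceneBundle, path: str | Path) -> Path:
    """Write a scene as a 4-band float64 TIFF plus key=value sidecar.

    Returns the sidecar path.
    """
    path = Path(path)
    stack = np.stack([bundle.bands[r] for r in BAND_ROLES])
    tifffile.imwrite(
        path, stack.astype(np.float64), photometric="minisblack", planarconfig="separate"
    )
    lines = [f"UNITS={bundle.units}"]
    for role in BAND_ROLES:
        up = role.upper()
        if bundle.gain is not None:
            lines.append(f"GAIN_{up}={bundle.gain[role]!r}")
        if bundle.bias is not None:
            lines.append(f"BIAS_{up}={bundle.bias[role]!r}")
        if bundle.esun is not None:
            lines.append(f"ESUN_{up}={bundle.esun[role]!r}")
    lines.append(f"SUN_ELEVATION={bundle.sun_elevation_deg!r}")
    lines.append(f"DOY={int(bundle.acquisition_doy)}")
    lines.append(f"PIXEL_SIZE={bundle.pixel_size_m!r}")
    if bundle.nodata_value is not None:
        lines.append(f"NODATA={bundle.nodata_value!r}")
    if bundle.year is not None:
        lines.append(f"YEAR={int(bundle.year)}")
    sidecar = _sidecar_path(path)
    sidecar.write_text("\n".join(lines) + "\n")
    return sidecar


def read_sidecar(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"malformed sidecar line: {raw!r}")
        key, value = line.split("=", 1)
        meta[key.strip().upper()] = value.strip()
    return meta


def read_scene(path: str | Path, meta_path: str | Path | None = None) -> SceneBundle:
    """Read a scene TIFF and its sidecar back into a :class:`SceneBundle`."""
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim != 3 or stack.shape[0] != len(BAND_ROLES):
        raise DimensionError(
            f"expected a {len(BAND_ROLES)}-band raster, got shape {stack.shape}"
        )
    meta = read_sidecar(meta_path if meta_path is not None else _sidecar_path(path))

    def _band_map(prefix: str) -> dict[str, float] | None:
        keys = {r: f"{prefix}_{r.upper()}" for r in BAND_ROLES}
        if not any(k in meta for k in keys.values()):
            return None
        try:
            return {r: float(meta[k]) for r, k in keys.items()}
        except KeyError as exc:
            raise ParameterError(f"sidecar missing per-band key {exc}") from exc

    return SceneBundle(
        bands={r: stack[i] for i, r in enumerate(BAND_ROLES)},
        units=meta.get("UNITS", UNITS_REFLECTANCE).lower(),
        gain=_band_map("GAIN"),
        bias=_band_map("BIAS"),
        esun=_band_map("ESUN"),
        sun_elevation_deg=float(meta["SUN_ELEVATION"]),
        acquisition_doy=int(meta["DOY"]),
        pixel_size_m=float(meta["PIXEL_SIZE"]),
        nodata_value=float(meta["NODATA"]) if "NODATA" in meta else None,
        year=int(meta["YEAR"]) if "YEAR" in meta else None,
    )


def write_singleband(
    grid: np.ndarray, path: str | Path, dtype=np.float32
) -> None:
    """Write a single-band grid (ratio map, mask, category map) as TIFF."""
    tifffile.imwrite(Path(path), np.asarray(grid).astype(dtype))
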