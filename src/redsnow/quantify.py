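"""Red-snow abundance categories, biomass conversion and summaries.

Snow pixels whose red:green reflectance ratio exceeds 1.0 carry a
significant red-algae load; a ratio of exactly 1.0 corresponds to an
algal cell-volume biomass of 100 ml m^-2, the anchor of a positive
linear ratio-to-biomass calibration. Ratios above 1.0 are binned into
five abundance categories (field observations place "bright red" snow
above a ratio of 1.02); each category contributes its area times its
mean biomass density to the scene total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError, ParameterError
from .reflectance import RatioMap
from .snow_mask import SnowMask, snow_area

#: Biomass density (ml m^-2) pinned at a red:green ratio of exactly 1.0.
ANCHOR_RATIO = 1.0
ANCHOR_BIOMASS_ML_M2 = 100.0

#: Default slope of the linear ratio->biomass calibration, ml m^-2 per
#: ratio unit. A stand-in for the field regression behind the anchor;
#: fully configurable.
DEFAULT_SLOPE = 5000.0

#: Default half-open ratio intervals (lo, hi] for the five abundance
#: categories; the first lower bound is the strict ratio > 1.0 rule and
#: 1.02 is the field-verified "bright red" level.
DEFAULT_CATEGORY_BOUNDS = (
    (1.00, 1.02),
    (1.02, 1.04),
    (1.04, 1.06),
    (1.06, 1.08),
    (1.08, float("inf")),
)

#: Representative ratio used to evaluate the mean biomass of the
#: unbounded top category.
TOP_CATEGORY_REPRESENTATIVE_RATIO = 1.09

#: Nodata code in category rasters (categories occupy 0-5).
CATEGORY_NODATA = 255


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear ratio-to-biomass model plus five abundance categories.

    ``biomass(r) = slope * r + intercept`` with the intercept always
    derived from the anchor (``biomass(1.0) = 100 ml m^-2``), so the
    anchor holds for every admissible slope. Category mean biomass
    defaults to the curve evaluated at each interval midpoint (top
    interval at :data:`TOP_CATEGORY_REPRESENTATIVE_RATIO`).
    """

    slope: float = DEFAULT_SLOPE
    category_bounds: tuple[tuple[float, float], ...] = DEFAULT_CATEGORY_BOUNDS
    category_mean_biomass: tuple[float, ...] | None = None
    anchor_ratio: float = ANCHOR_RATIO
    anchor_biomass: float = ANCHOR_BIOMASS_ML_M2

    def __post_init__(self) -> None:
        bounds = tuple(tuple(b) for b in self.category_bounds)
        if len(bounds) != 5:
            raise ConfigError("exactly five category intervals are required")
        if self.anchor_ratio < bounds[0][0]:
            raise ConfigError(
                "ratio threshold below the first category bound leaves ratios "
                f"in ({self.anchor_ratio}, {bounds[0][0]}] uncategorized"
            )
        for (lo, hi), (lo2, _hi2) in zip(bounds, bounds[1:]):
            if not lo < hi:
                raise ConfigError(f"empty category interval ({lo}, {hi}]")
            if hi != lo2:
                raise ConfigError("category intervals must be contiguous")
        if not np.isinf(bounds[-1][1]) and not bounds[-1][0] < bounds[-1][1]:
            raise ConfigError("top category interval is empty")
        object.__setattr__(self, "category_bounds", bounds)
        if self.slope < 0:
            raise ConfigError("the ratio-biomass correlation is positive; slope >= 0")
        if self.category_mean_biomass is None:
            mids = [
                (lo + hi) / 2 if np.isfinite(hi) else TOP_CATEGORY_REPRESENTATIVE_RATIO
                for lo, hi in bounds
            ]
            # midpoint means of a nonnegative-slope line are automatically
            # nondecreasing; ties only occur for the degenerate slope 0
            means = tuple(self.biomass_at_ratio(m) for m in mids)
            object.__setattr__(self, "category_mean_biomass", means)
        else:
            means = tuple(float(m) for m in self.category_mean_biomass)
            if len(means) != 5:
                raise ConfigError("five category mean biomass values are required")
            if not all(a < b for a, b in zip(means, means[1:])):
                raise ConfigError("category mean biomass must be strictly increasing")
            object.__setattr__(self, "category_mean_biomass", means)

    @property
    def intercept(self) -> float:
        """ml m^-2; constrained so the anchor ratio maps to the anchor biomass."""
        return self.anchor_biomass - self.slope * self.anchor_ratio

    def biomass_at_ratio(self, ratio: float) -> float:
        """Biomass density (ml m^-2) predicted at a red:green ratio."""
        if not ratio > 0:
            raise ParameterError("ratio must be positive")
        return self.slope * ratio + self.intercept

    def category_of(self, ratio: np.ndarray) -> np.ndarray:
        """Vectorized category lookup: 0 for ratio <= threshold, else 1-5."""
        ratio = np.asarray(ratio, dtype=float)
        edges = [lo for lo, _ in self.category_bounds] + [self.category_bounds[-1][1]]
        # (lo, hi] intervals: searchsorted with side="left" on the lower
        # edges puts a value equal to an edge into the lower category.
        cat = np.searchsorted(np.asarray(edges[:-1]), ratio, side="left")
        cat = np.where(ratio <= self.anchor_ratio, 0, np.maximum(cat, 1))
        return np.minimum(cat, 5).astype(np.int64)


def biomass_at_ratio(ratio: float, calib: CalibrationCurve | None = None) -> float:
    """Module-level convenience for :meth:`CalibrationCurve.biomass_at_ratio`."""
    calib = calib if calib is not None else CalibrationCurve()
    return calib.biomass_at_ratio(ratio)


@dataclass
class CategoryMap:
    """Per-pixel abundance category: 0 = snow without significant algae,
    1-5 = increasing red-snow abundance, 255 = nodata/non-snow."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)

    def category_counts(self) -> np.ndarray:
        """Pixel counts for categories 1..5."""
        valid = self.values[self.values != CATEGORY_NODATA]
        return np.bincount(valid.astype(int), minlength=6)[1:6]


def classify_categories(
    ratio: RatioMap, mask: SnowMask, calib: CalibrationCurve | None = None
) -> CategoryMap:
    """Assign each snow pixel its red-snow abundance category.

    Non-snow or nodata pixels get the nodata code; snow pixels with a
    ratio <= 1.0 (strict threshold) get category 0; the rest fall into
    the category whose (lo, hi] interval contains the ratio.
    """
    calib = calib if calib is not None else CalibrationCurve()
    if ratio.values.shape != mask.mask.shape:
        raise DimensionError("ratio map and snow mask differ in shape")
    valid = mask.mask & ~ratio.nodata
    cat = np.full(ratio.values.shape, CATEGORY_NODATA, dtype=np.uint8)
    vals = ratio.values[valid]
    cat[valid] = calib.category_of(vals).astype(np.uint8)
    return CategoryMap(values=cat)


@dataclass
class BiomassSummary:
    """Per-scene snow area, category areas, biomass and percent cover."""

    snow_area_m2: float
    area_per_category_m2: tuple[float, float, float, float, float]
    total_biomass_ml: float
    percent_snow_with_algae: float
    percent_per_category: tuple[float, float, float, float, float]

    def to_dict(self) -> dict:
        return {
            "snow_area_m2": self.snow_area_m2,
            "area_per_category_m2": list(self.area_per_category_m2),
            "total_biomass_ml": self.total_biomass_ml,
            "total_biomass_l": self.total_biomass_ml / 1000.0,
            "percent_snow_with_algae": self.percent_snow_with_algae,
            "percent_per_category": list(self.percent_per_category),
        }


def summarize(
    catmap: CategoryMap,
    mask: SnowMask,
    calib: CalibrationCurve | None = None,
    pixel_size_m: float = 30.0,
) -> BiomassSummary:
    """Areas, total biomass and percent cover from a category map.

    Total biomass sums area_k x mean_biomass_k over the five
    categories; percent cover divides the algae-bearing snow area by
    the total snow area. A snow-free scene reports 0% with a warning.
    """
    calib = calib if calib is not None else CalibrationCurve()
    if catmap.values.shape != mask.mask.shape:
        raise DimensionError("category map and snow mask differ in shape")
    pixel_area = pixel_size_m * pixel_size_m
    total_snow = snow_area(mask, pixel_size_m)
    counts = catmap.category_counts()
    areas = tuple(float(c) * pixel_area for c in counts)
    biomass = float(
        sum(a * m for a, m in zip(areas, calib.category_mean_biomass))
    )
    algae_area = float(sum(areas))
    if total_snow > 0:
        percent = 100.0 * algae_area / total_snow
        per_cat = tuple(100.0 * a / total_snow for a in areas)
    else:
        if algae_area > 0:
            raise ParameterError("algae area without snow area violates masking")
        warnings.warn("scene has no snow pixels; percent cover reported as 0")
        percent = 0.0
        per_cat = (0.0,) * 5
    return BiomassSummary(
        snow_area_m2=total_snow,
        area_per_category_m2=areas,
        total_biomass_ml=biomass,
        percent_snow_with_algae=percent,
        percent_per_category=per_cat,
    )


def percent_change(value_old: float, value_new: float) -> float:
    """Relative change in percent, 100 * (new - old) / old; old must be > 0."""
    if not value_old > 0:
        raise ParameterError("percent change requires a positive baseline value")
    return 100.0 * (value_new - value_old) / value_old


def timeseries_report(
    summaries: list[tuple[int, BiomassSummary]]
) -> pd.DataFrame:
    """Percent changes between consecutive annual summaries.

    One row per consecutive year pair with percent change of total
    biomass, snow area, and algal percent cover (cover change is in
    relative percent of the older cover value). Years must be strictly
    increasing.
    """
    if len(summaries) < 2:
        raise ParameterError("time series needs at least two dated summaries")
    years = [y for y, _ in summaries]
    if any(a >= b for a, b in zip(years, years[1:])):
        raise ParameterError(f"years must be strictly increasing, got {years}")
    rows = []
    for (y0, s0), (y1, s1) in zip(summaries, summaries[1:]):
        rows.append(
            {
                "year_from": y0,
                "year_to": y1,
                "biomass_change_pct": percent_change(
                    s0.total_biomass_ml, s1.total_biomass_ml
                )
                if s0.total_biomass_ml > 0
                else float("nan"),
                "snow_area_change_pct": percent_change(s0.snow_area_m2, s1.snow_area_m2)
                if s0.snow_area_m2 > 0
                else float("nan"),
                "percent_cover_change_pct": percent_change(
                    s0.percent_snow_with_algae, s1.percent_snow_with_algae
                )
                if s0.percent_snow_with_algae > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
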