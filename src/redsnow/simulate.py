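"""Ground-truthed synthetic scenes and community count tables.

Every downstream stage of the pipeline is tested against data whose
answer is known exactly. Scenes are composed of water, bare ground,
white snow and five red-snow abundance classes; each class's band
reflectances are constructed to satisfy the detection thresholds
(NDSI > 0.4, NIR > 0.11, red:green ratio rules) with a margin, so the
classifier must recover the generator's labels pixel for pixel.
Red-snow pixels draw their red:green ratio uniformly inside the target
category interval and back-solve the red reflectance from the green
band, which guarantees classifiability for any noise realization.

Gaussian reflectance noise is *re-sampled* (truncated), never clipped,
for pixels that a noise draw pushes across a decision boundary: the
thresholds are strict inequalities, so probability mass exactly on a
boundary would make labels ambiguous.

Count tables emulate red-vs-white-snow metagenome profiles: log-normal
per-feature abundances, a configurable number of differential features
shifted by a log-fold effect between groups, and multinomial read
sampling to a per-sample depth drawn from a realistic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CountTable
from .errors import ParameterError
from .quantify import CalibrationCurve
from .scene import BAND_ROLES, UNITS_DN, UNITS_REFLECTANCE, SceneBundle

#: Scene class labels in canonical order; integer codes are positional.
SCENE_CLASSES = (
    "water",
    "bare",
    "white_snow",
    "red_cat1",
    "red_cat2",
    "red_cat3",
    "red_cat4",
    "red_cat5",
)

#: Default scene composition: a coastal snowfield with a modest algal bloom.
DEFAULT_CLASS_FRACTIONS = {
    "water": 0.20,
    "bare": 0.10,
    "white_snow": 0.50,
    "red_cat1": 0.08,
    "red_cat2": 0.05,
    "red_cat3": 0.03,
    "red_cat4": 0.02,
    "red_cat5": 0.02,
}

# Base reflectances (green, red, nir, swir) per class, chosen with a
# comfortable margin from the NDSI/NIR/ratio thresholds. Red-snow and
# white-snow pixels get their red band from a sampled ratio instead.
_BASE_REFLECTANCE = {
    "water": {"green": 0.06, "red": 0.04, "nir": 0.04, "swir": 0.02},
    "bare": {"green": 0.18, "red": 0.20, "nir": 0.30, "swir": 0.24},
    "white_snow": {"green": 0.85, "red": None, "nir": 0.65, "swir": 0.08},
    "red_snow": {"green": 0.60, "red": None, "nir": 0.45, "swir": 0.06},
}

#: White snow red:green ratio sampling interval (strictly below 1.0).
_WHITE_RATIO_RANGE = (0.90, 0.99)
#: Cap for ratio sampling in the unbounded top category.
_TOP_RATIO_CAP = 1.15
#: Margin keeping sampled ratios off the half-open interval edges.
_RATIO_EDGE_MARGIN = 1e-4

# Landsat-TM-style radiometric constants used when emitting DN bundles.
DEFAULT_GAIN = {"green": 0.8, "red": 0.8, "nir": 0.9, "swir": 0.12}
DEFAULT_BIAS = {"green": -2.0, "red": -2.0, "nir": -2.0, "swir": -0.3}
DEFAULT_ESUN = {"green": 1796.0, "red": 1536.0, "nir": 1031.0, "swir": 220.0}

_MAX_RESAMPLE_ROUNDS = 200


@dataclass
class SceneParams:
    """Composition and noise parameters for one synthetic scene."""

    n_rows: int = 128
    n_cols: int = 128
    pixel_size_m: float = 30.0
    class_fractions: dict[str, float] | None = None
    reflectance_noise_sd: float = 0.0
    sun_elevation_deg: float = 35.0
    acquisition_doy: int = 220
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("scene must have at least one row and column")
        if self.reflectance_noise_sd < 0:
            raise ParameterError("reflectance_noise_sd must be nonnegative")
        if self.class_fractions is None:
            self.class_fractions = dict(DEFAULT_CLASS_FRACTIONS)
        unknown = set(self.class_fractions) - set(SCENE_CLASSES)
        if unknown:
            raise ParameterError(f"unknown scene classes: {sorted(unknown)}")
        fracs = {c: float(self.class_fractions.get(c, 0.0)) for c in SCENE_CLASSES}
        if any(v < 0 for v in fracs.values()):
            raise ParameterError("class fractions must be nonnegative")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ParameterError(
                f"class fractions must sum to 1, got {sum(fracs.values())!r}"
            )
        self.class_fractions = fracs


@dataclass
class SceneTruth:
    """Generator bookkeeping: the labels and summary values a correct
    quantification must recover exactly (on noise-free scenes)."""

    class_labels: np.ndarray  # int codes indexing SCENE_CLASSES
    pixel_size_m: float
    true_snow_area_m2: float
    true_area_per_category_m2: tuple[float, float, float, float, float]
    true_total_biomass_ml: float

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.class_labels.ravel(), minlength=len(SCENE_CLASSES))
        return {c: int(n) for c, n in zip(SCENE_CLASSES, counts)}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pixel_size_m": self.pixel_size_m,
            "true_snow_area_m2": self.true_snow_area_m2,
            "true_area_per_category_m2": list(self.true_area_per_category_m2),
            "true_total_biomass_ml": self.true_total_biomass_ml,
            "class_counts": self.class_counts(),
            "class_labels": self.class_labels.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _apportion_pixels(n_pixels: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so class areas sum exactly."""
    quotas = {c: n_pixels * f for c, f in fractions.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n_pixels - sum(counts.values())
    remainders = sorted(
        fractions, key=lambda c: (quotas[c] - counts[c], c), reverse=True
    )
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def _label_ok(
    labels: np.ndarray,
    bands: dict[str, np.ndarray],
    calib: CalibrationCurve,
) -> np.ndarray:
    """Per-pixel check that noisy reflectances still match the label."""
    green, red = bands["green"], bands["red"]
    nir, swir = bands["nir"], bands["swir"]
    positive = (green > 0) & (red > 0) & (nir > 0) & (swir > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndsi = (green - swir) / (green + swir)
        ratio = red / green
    is_snowlike = (ndsi > 0.4) & (nir > 0.11)
    ok = np.zeros(labels.shape, dtype=bool)
    water = labels == SCENE_CLASSES.index("water")
    bare = labels == SCENE_CLASSES.index("bare")
    white = labels == SCENE_CLASSES.index("white_snow")
    ok[water] = positive[water] & (nir[water] <= 0.11)
    ok[bare] = positive[bare] & (ndsi[bare] <= 0.4)
    ok[white] = positive[white] & is_snowlike[white] & (ratio[white] <= 1.0)
    cat = calib.category_of(np.where(positive, ratio, 1.0))
    for k in range(1, 6):
        sel = labels == SCENE_CLASSES.index(f"red_cat{k}")
        ok[sel] = positive[sel] & is_snowlike[sel] & (cat[sel] == k)
    return ok


def generate_scene(
    params: SceneParams, calib: CalibrationCurve | None = None
) -> tuple[SceneBundle, SceneTruth]:
    """Generate one reflectance scene with exact truth bookkeeping.

    Returns a reflectance-units :class:`SceneBundle` (use
    :func:`as_digital_numbers` to exercise the DN conversion path) and
    the matching :class:`SceneTruth`. Deterministic for a fixed seed.
    """
    calib = calib if calib is not None else CalibrationCurve()
    rng = np.random.default_rng(params.seed)
    n_pixels = params.n_rows * params.n_cols
    counts = _apportion_pixels(n_pixels, params.class_fractions)

    labels = np.repeat(
        [SCENE_CLASSES.index(c) for c in SCENE_CLASSES],
        [counts[c] for c in SCENE_CLASSES],
    )
    rng.shuffle(labels)
    labels = labels.reshape(params.n_rows, params.n_cols)

    bands = {r: np.zeros(labels.shape, dtype=float) for r in BAND_ROLES}

    def _fill(sel: np.ndarray, base_key: str, ratio_range: tuple[float, float] | None):
        n = int(sel.sum())
        if n == 0:
            return
        base = _BASE_REFLECTANCE[base_key]
        for role in ("green", "nir", "swir"):
            bands[role][sel] = base[role]
        if ratio_range is None:
            bands["red"][sel] = base["red"]
        else:
            lo, hi = ratio_range
            ratios = rng.uniform(lo, hi, size=n)
            bands["red"][sel] = ratios * base["green"]

    _fill(labels == SCENE_CLASSES.index("water"), "water", None)
    _fill(labels == SCENE_CLASSES.index("bare"), "bare", None)
    _fill(labels == SCENE_CLASSES.index("white_snow"), "white_snow", _WHITE_RATIO_RANGE)
    for k, (lo, hi) in enumerate(calib.category_bounds, start=1):
        hi_eff = min(hi, _TOP_RATIO_CAP)
        _fill(
            labels == SCENE_CLASSES.index(f"red_cat{k}"),
            "red_snow",
            (lo + _RATIO_EDGE_MARGIN, hi_eff),
        )

    if params.reflectance_noise_sd > 0:
        sd = params.reflectance_noise_sd
        noisy = {r: bands[r] + rng.normal(0.0, sd, labels.shape) for r in BAND_ROLES}
        bad = ~_label_ok(labels, noisy, calib)
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > _MAX_RESAMPLE_ROUNDS:
                raise ParameterError(
                    "reflectance_noise_sd too large: noise keeps pushing pixels "
                    "across classification thresholds"
                )
            n_bad = int(bad.sum())
            for r in BAND_ROLES:
                noisy[r][bad] = bands[r][bad] + rng.normal(0.0, sd, n_bad)
            still = ~_label_ok(labels, noisy, calib)
            bad &= still
        bands = noisy

    assert _label_ok(labels, bands, calib).all()

    bundle = SceneBundle(
        bands=bands,
        units=UNITS_REFLECTANCE,
        sun_elevation_deg=params.sun_elevation_deg,
        acquisition_doy=params.acquisition_doy,
        pixel_size_m=params.pixel_size_m,
        gain=dict(DEFAULT_GAIN),
        bias=dict(DEFAULT_BIAS),
        esun=dict(DEFAULT_ESUN),
    )

    pixel_area = params.pixel_size_m**2
    cat_areas = tuple(
        counts[f"red_cat{k}"] * pixel_area for k in range(1, 6)
    )
    snow_area = counts["white_snow"] * pixel_area + sum(cat_areas)
    biomass = float(
        sum(a * m for a, m in zip(cat_areas, calib.category_mean_biomass))
    )
    truth = SceneTruth(
        class_labels=labels,
        pixel_size_m=params.pixel_size_m,
        true_snow_area_m2=float(snow_area),
        true_area_per_category_m2=cat_areas,
        true_total_biomass_ml=biomass,
    )
    return bundle, truth


def as_digital_numbers(bundle: SceneBundle) -> SceneBundle:
    """Re-encode a reflectance bundle as (float) digital numbers.

    Inverts the TOA reflectance formula with the bundle's gain/bias/
    ESUN metadata so that converting back recovers the reflectances
    exactly; DN values are left unquantized.
    """
    if bundle.units != UNITS_REFLECTANCE:
        raise ParameterError("expected a reflectance bundle")
    if bundle.gain is None or bundle.bias is None or bundle.esun is None:
        raise ParameterError("bundle lacks gain/bias/ESUN metadata")
    from .reflectance import earth_sun_distance  # local import avoids cycle

    d = earth_sun_distance(bundle.acquisition_doy)
    cosz = np.cos(np.radians(90.0 - bundle.sun_elevation_deg))
    dn_bands = {}
    for role in BAND_ROLES:
        radiance = bundle.bands[role] * bundle.esun[role] * cosz / (np.pi * d * d)
        dn_bands[role] = (radiance - bundle.bias[role]) / bundle.gain[role]
    return bundle.with_bands(dn_bands, UNITS_DN)


@dataclass
class CountSimParams:
    """Parameters for the two-group community count-table simulator.

    Defaults mirror the red-vs-white-snow comparison scale: five
    samples per group, 100 features of which 30 differ between groups
    with a log-fold effect of 2, and sequencing depths in the range of
    the quality-filtered snow metagenome libraries.
    """

    n_samples_per_group: int = 5
    n_features: int = 100
    n_differential: int = 30
    log_fold_effect: float = 2.0
    base_abundance_dispersion: float = 1.0
    sequencing_depth_range: tuple[int, int] = (40_000, 120_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_features < 1:
            raise ParameterError("need at least one sample per group and one feature")
        if not (0 <= self.n_differential <= self.n_features):
            raise ParameterError("n_differential must be in [0, n_features]")
        lo, hi = self.sequencing_depth_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ParameterError("sequencing depths must be positive with lo <= hi")
        if self.base_abundance_dispersion < 0:
            raise ParameterError("dispersion must be nonnegative")


def generate_count_table(params: CountSimParams) -> CountTable:
    """Simulate a red-snow vs white-snow sample-by-feature count table.

    Per-feature log abundances are normal (log-normal abundances); the
    first ``n_differential`` features are shifted by ``log_fold_effect``
    between groups, alternating direction so the shift is not a pure
    depth artifact; reads are drawn multinomially to a per-sample depth
    uniform over ``sequencing_depth_range``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples_per_group
    p = params.n_features

    log_mu = rng.normal(0.0, params.base_abundance_dispersion, size=p)
    shift = np.zeros(p)
    signs = np.where(np.arange(params.n_differential) % 2 == 0, 1.0, -1.0)
    shift[: params.n_differential] = signs * params.log_fold_effect

    group_logmu = {"red_snow": log_mu + shift, "white_snow": log_mu}
    feature_ids = [f"feature_{i + 1:04d}" for i in range(p)]
    sample_ids, group_labels, columns = [], [], []
    lo, hi = params.sequencing_depth_range
    for group, prefix in (("red_snow", "red"), ("white_snow", "white")):
        probs = np.exp(group_logmu[group])
        probs = probs / probs.sum()
        for i in range(n):
            depth = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(depth, probs)
            sample_ids.append(f"{prefix}_{i + 1}")
            group_labels.append(group)
            columns.append(counts)
    counts = pd.DataFrame(
        np.column_stack(columns), index=feature_ids, columns=sample_ids
    )
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    return CountTable(counts=counts, groups=groups)
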