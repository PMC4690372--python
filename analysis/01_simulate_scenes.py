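#!/usr/bin/env python
"""Generate a four-year trajectory of synthetic satellite scenes.

Emulates a coastal snowfield where a red-snow bloom expands over two
decades and then collapses while total snow cover declines: the
red-snow fraction roughly doubles between the first two acquisitions,
grows slightly, then drops by about two thirds. Scenes are written as
4-band TIFFs with metadata sidecars plus exact truth bookkeeping under
results/scenes/.
"""

from pathlib import Path

from redsnow import SceneParams, generate_scene, write_scene

OUT = Path(__file__).resolve().parents[1] / "results" / "scenes"

# year -> scene composition (fractions sum to 1); snow cover declines
# while the algal fraction rises then falls
TRAJECTORY = {
    1986: {"water": 0.15, "bare": 0.05, "white_snow": 0.75, "red_cat1": 0.05},
    2002: {"water": 0.20, "bare": 0.05, "white_snow": 0.638, "red_cat1": 0.112},
    2006: {"water": 0.25, "bare": 0.05, "white_snow": 0.5712, "red_cat1": 0.1288},
    2015: {"water": 0.35, "bare": 0.10, "white_snow": 0.50234, "red_cat1": 0.04766},
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for year, fractions in TRAJECTORY.items():
        bundle, truth = generate_scene(
            SceneParams(
                n_rows=128,
                n_cols=128,
                class_fractions=fractions,
                reflectance_noise_sd=0.01,
                seed=year,
            )
        )
        bundle.year = year
        write_scene(bundle, OUT / f"scene_{year}.tif")
        truth.to_json(OUT / f"truth_{year}.json")
        print(
            f"{year}: snow {truth.true_snow_area_m2 / 1e6:.2f} km^2, "
            f"red-snow biomass {truth.true_total_biomass_ml / 1e6:.2f} kl"
        )
    print(f"wrote {len(TRAJECTORY)} scenes under {OUT}")


if __name__ == "__main__":
    main()
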