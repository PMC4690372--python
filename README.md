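# redsnow

Quantify red-snow algae in multiband satellite imagery and compare
snow microbial communities.

Blooms of the snow alga *Chlamydomonas nivalis* color polar and alpine
snowfields red ("watermelon snow"). The astaxanthin-pigmented cells
reflect more strongly in the red band (630–690 nm) than in the green
band (520–600 nm), the reverse of clean snow and ice, so the per-pixel
red:green top-of-atmosphere reflectance ratio separates red snow
(ratio > 1.0) from white snow (ratio < 1.0). Because red snow lowers
albedo and accelerates melt, mapping its extent and biomass over time
matters for snow-cover and carbon-cycle studies.

`redsnow` implements the full chain from raw Landsat-style digital
numbers to an algal biomass summary, plus the permutation statistics
used to contrast red-snow and white-snow microbial communities:

- **Reflectance**: DN → radiance (`L = gain·DN + bias`) → TOA
  reflectance `ρ = π·L·d²/(ESUN·cos θs)`, with the earth–sun distance
  `d` from the standard day-of-year cosine approximation.
- **Snow masking**: a pixel is snow/ice iff
  `NDSI = (green − SWIR)/(green + SWIR) > 0.4` **and** NIR reflectance
  `> 0.11` (the NIR test screens out water); both inequalities strict.
- **Red-snow quantification**: snow pixels with red:green ratio > 1.0
  carry significant algae; a ratio of exactly 1.0 corresponds to an
  algal cell volume of 100 ml m⁻², the anchor of a linear
  ratio→biomass calibration. Ratios are binned into five abundance
  categories (field work places "bright red" snow above 1.02); total
  biomass is Σₖ areaₖ · mean-biomassₖ, and percent cover divides
  algae-bearing snow area by total snow area. A time-series report
  gives percent changes between acquisitions.
- **Community statistics** (implemented from scratch): common-depth
  normalization with ln(x+1), Bray–Curtis dissimilarity
  `d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`, PERMANOVA with pseudo-F
  `(SS_B/(a−1))/(SS_W/(N−a))` and an exhaustive-enumeration fallback
  for small designs, SIMPROF pruning of average-linkage dendrograms,
  column-centered PCA, and per-feature one-way ANOVA with
  Benjamini–Hochberg adjustment.
- **Synthetic data**: ground-truthed scene and count-table generators,
  so every stage is testable without external scene downloads.

## Worked example

Simulate a four-scene bloom trajectory and quantify it:

```sh
python analysis/01_simulate_scenes.py
python analysis/02_quantify_timeseries.py
```

prints the per-year summaries and the consecutive changes:

```
 year  snow_area_m2  total_biomass_ml  total_biomass_l  percent_snow_with_algae
 1986    11796300.0       110565000.0         110565.0                 6.248569
 2002    11059200.0       247725000.0         247725.0                14.933268
 2006    10322100.0       284850000.0         284850.0                18.397419
 2015     8109900.0       105435000.0         105435.0                 8.667185

 year_from  year_to  biomass_change_pct  snow_area_change_pct  percent_cover_change_pct
      1986     2002               124.1                  -6.2                     139.0
      2002     2006                15.0                  -6.7                      23.2
      2006     2015               -63.0                 -21.4                     -52.9
```

Total snow area shrinks monotonically while algal biomass first grows
(+124%, +15%) and then collapses (−63%); percent cover shows algae
occupying a growing share of the remaining snow until the collapse.
On noise-free synthetic scenes these summaries match the generator's
truth bookkeeping exactly (areas bit-identical, biomass to 1e-9).

Compare simulated red-snow vs white-snow communities:

```sh
python analysis/03_simulate_counts.py
python analysis/04_community_comparison.py
```

```
PERMANOVA: pseudo-F = 839.784, p = 0.0079 (exhaustive, 252 label arrangements)
SIMPROF: 5 significant clusters
PCA (top 10 variable features): PC1+PC2 explain 99.7% of variance
per-feature ANOVA: 100/100 features at q <= 0.05
```

With 5+5 samples there are only 252 distinct label arrangements, so
the PERMANOVA p-value is enumerated exactly; p = 2/252 ≈ 0.0079 is the
smallest attainable value for this design.

The same stages are available as a CLI
(`redsnow simulate-scene | simulate-counts | quantify | timeseries |
compare`) with a YAML config file and per-flag overrides; see
`redsnow --help`. Real Landsat scenes can be quantified by pointing
`redsnow quantify` at a 4-band TIFF (green/red/NIR/SWIR) with a
`key=value` metadata sidecar (gain/bias/ESUN per band, sun elevation,
day of year, pixel size).

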