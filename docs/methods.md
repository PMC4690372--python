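# Methods

## Raster chain

**Radiometry.** Digital numbers are rescaled to at-sensor radiance
`L = gain·DN + bias` and to top-of-atmosphere reflectance
`ρ = π·L·d²/(ESUN·cos θs)`. The earth–sun distance uses the day-angle
cosine approximation `d = 1 − 0.01672·cos(0.9856°·(doy − 4))` rather
than an ephemeris table; its error is below 0.1%, negligible against
sensor calibration uncertainty. The solar zenith `θs = 90° − sun
elevation` is taken once per scene from the metadata sidecar, matching
the granularity of Landsat scene metadata. Reflectance is deliberately
**not clamped** to [0, 1]: bright snow can exceed 1 and clamping would
bias red:green ratios downward over exactly the surfaces of interest.
Band roles (green 520–600 nm, red 630–690 nm, NIR, SWIR) are declared
by role in the sidecar, so TM/ETM+/OLI band-numbering differences are
a configuration concern, not a code path.

**Snow mask.** `NDSI = (green − SWIR)/(green + SWIR)`; a pixel is
snow/ice iff NDSI > 0.4 and NIR reflectance > 0.11 (the NIR screen
removes water, which can show high NDSI but is dark in the near
infrared). Both comparisons are strict, so boundary pixels are
excluded; nodata in any contributing band excludes the pixel
(conservative). The NDSI test is applied to reflectance, not DN.

**Ratio, categories, biomass.** The red:green reflectance ratio is
computed per pixel; green ≤ 0 or nodata in either band yields nodata.
Snow pixels with ratio > 1.0 (strict) carry significant red algae.
The ratio→biomass calibration is the line `b(r) = slope·r + intercept`
with the intercept always derived from the anchor `b(1.0) = 100 ml
m⁻²`, so the anchor holds identically for every admissible slope.
Ratios above 1.0 fall into five half-open categories, by default
(1.00, 1.02], (1.02, 1.04], (1.04, 1.06], (1.06, 1.08], (1.08, ∞) —
1.02 is the field-verified "bright red" level; right-closed intervals
make the strict >1.0 rule and the category partition mutually
exclusive and exhaustive. Category mean biomass defaults to the
calibration evaluated at interval midpoints (top interval represented
at 1.09) with a default slope of 5 000 ml m⁻² per ratio unit; the
slope, bounds and means are all configurable and the defaults are a
documented stand-in for a field regression: absolute biomass totals
should be read as calibration-dependent, while areas, percent cover
and percent changes are not. Totals are reported in ml (density ml m⁻²
× area m²) with liters in human-readable output. Raising the ratio
threshold above 1.0 (e.g. to 1.02) reclassifies the bypassed ratios as
category 0 without renumbering the remaining categories.

**Summaries and change.** Snow area is (snow-pixel count)·(pixel
size)²; per-category areas likewise; total biomass Σₖ areaₖ·meanₖ;
percent cover 100·Σareaₖ/snow area (0 with a warning on a snow-free
scene). Percent change is 100·(new − old)/old and requires a positive
baseline. Biomass is summed over snow-masked pixels only; red-ratio
pixels outside the snow mask (e.g. wet rock) are excluded.

## Synthetic scenes

The generator emulates a coastal snowfield: water, bare ground, white
snow and five red-snow classes in configurable fractions. Pixel counts
come from largest-remainder apportionment, so class areas always sum
exactly to the scene area; positions are shuffled with the seed. Each
class's base reflectances sit with a comfortable margin on the correct
side of every threshold; red-snow pixels draw their ratio uniformly
inside the target category interval and back-solve the red band from
the green band, which makes category membership hold by construction.
Gaussian band noise is applied per pixel and **re-sampled** (truncated)
wherever a draw would push a pixel across a decision boundary — the
thresholds are strict inequalities, so clipping would concentrate mass
exactly on ambiguous boundary values; noise too large to satisfy the
labels within 200 rounds is a parameter error. Scenes can be emitted
as reflectance or as digital numbers via the exact inverse of the TOA
formula; DN values are left unquantized floats so the DN path is a
pure round-trip (integer quantization would only add an epsilon with
no scientific content). What passing tests show is therefore exact
recovery of a *consistent* scene; real scenes add atmosphere, mixed
pixels, clouds and terrain shading, which are out of scope.

## Count-table simulator

Per-feature log abundances are normal with configurable dispersion
(log-normal abundances); the first `n_differential` features are
shifted by `log_fold_effect` between groups, alternating sign so the
effect is not a pure depth artifact; reads are multinomial to a
per-sample depth drawn uniformly from `sequencing_depth_range`
(default 40 000–120 000, the order of quality-filtered snow metagenome
libraries). Defaults (5+5 samples, 100 features, 30 differential,
effect 2.0) are the conditions of the power analysis in the test
suite. No phylogenetic correlation structure is simulated.

## Community statistics

**Normalization.** "Similar numbers of reads per sample" is
implemented as deterministic rescaling of every sample to the minimum
sample total, then `ln(x + 1)` (natural log, pseudocount 1, zeros
preserved); rarefaction subsampling is available as a seeded option,
and per-feature z-scoring as an optional extra step. A zero-total
sample is a data error naming the sample.

**Bray–Curtis.** `d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`, 0 for two all-zero
samples by convention; symmetric, zero-diagonal, in [0, 1].

**PERMANOVA.** `SS_total = Σᵢ<ⱼ d²ᵢⱼ/N`, within-group sums analogous
per group divided by group size, `pseudo-F = (SS_B/(a−1))/(SS_W/(N−a))`.
The p-value permutes group labels; when the number of distinct label
arrangements is ≤ the requested permutations the null is enumerated
exhaustively (p = fraction of arrangements with F ≥ observed, observed
included), otherwise Monte-Carlo with the observed statistic in
numerator and denominator so p > 0 always. `SS_W = 0` with separation
yields F = ∞ (flagged, p still valid); an all-zero distance matrix is
degenerate (p = 1 with a warning). Ties in F are resolved with a 1e-12
tolerance toward counting the permutation as extreme.

**SIMPROF.** Average-linkage clustering on Bray–Curtis distances;
at each node the ordered observed dissimilarities are compared to the
mean ordered profile under within-feature permutation (each feature's
values shuffled independently across the node's samples, destroying
multivariate structure while preserving marginals); the statistic
π = Σ|d₍ᵢ₎ − ē₍ᵢ₎| is referred to a null from further permutations
(defaults 1000 expected / 999 test). Recursion descends only through
significant nodes (p ≤ α, default 0.05); groups of fewer than three
samples are untestable and returned as-is, so the output is always a
partition. Note that at metagenome-scale depths the test is extremely
sensitive: multinomial counting noise is tiny relative to any real
abundance difference, so even modest within-group heterogeneity splits
into sub-clusters. The same closure effect makes per-feature tests on
depth-normalized data sensitive to shifts in *other* features —
expected behavior for compositional data, worth remembering when
reading "significant" counts.

**PCA.** Samples are observations; columns (features) are centered,
not scaled; decomposition by SVD; percent variance = component
variance / total variance × 100, summing to 100 over all components.

**ANOVA.** One-way fixed-effects F per feature on normalized values,
BH-adjusted q alongside raw p (the package default multiplicity
control; α = 0.05). Zero within-variance with equal means gives F = 0,
p = 1; with unequal means the separation is perfect and p is reported
as the smallest positive float with a `degenerate` flag.

## Numerical and design choices

- Strict inequalities everywhere the rules say "greater than";
  boundary pixels and ratio = 1.0 are excluded by 1 000-case boundary
  tests.
- Raster I/O is plain multiband float64 TIFF plus a flat `key=value`
  sidecar; float64 keeps the ratio/threshold comparisons exact through
  a write/read round trip. No reprojection, mosaicking, atmospheric
  correction or cloud masking.
- Variance ties in top-k feature selection break by feature ID, so
  selection is deterministic.
- All stochastic routines take explicit seeds, which are embedded in
  every JSON report together with a config hash and the package
  version; re-runs are byte-identical.
- Problem sizes in the test suite (128×128 scenes, 200-replicate null
  simulations, 100-seed power runs) were chosen as the smallest sizes
  at which the checked properties are sharp: apportionment exactness
  does not depend on scene size, and the binomial bounds used for
  type-I checks account for the replicate counts.

## Limitations

Absolute biomass depends on a calibration whose slope and category
means are stand-ins unless field-regression values are supplied.
Scene analysis assumes co-registered, cloud-free, atmospherically
uncorrected TOA imagery and scene-level solar geometry. The community
statistics assume exchangeable samples under the null; none of the
tests model phylogenetic or spatial autocorrelation.
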