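# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `fieldscale` pipeline. Everything quantitative stated
here is computed by the test suite or `scripts/acceptance.py`.

## 1. The synthetic trial

The generator (`fieldscale.synthetic`) emulates a randomized-block tomato
trial: treatments 100/80/40% plant available water (PAW), three plots per
treatment, imaging campaigns at DAT 43, 47, 50, 56, 62, 66, 74, 81, 89
(the physiological sampling grid of such trials), and continuous bioristor
monitoring over DAT 30–90 at 15-minute sampling. Two monitoring layouts
are supported: `monitored="paper"` (five replicate sensors on one plot per
treatment, the field layout) and `monitored="all"` (one sensor per plot,
used when pooled plot-date statistics need n ≥ 50).

### Latent stress severity

All channels derive from one latent severity per treatment and day,

    s(t, DAT) = base + amplitude_t · clip((DAT − onset)/ramp_days, 0, 1)

with `base = 0.1`, `onset = 65` DAT, `ramp_days = 20` and amplitudes
0 / 0.1 / 0.8 for 100/80/40% PAW. Pre-onset severities are equal across
treatments by design, so the bioristor divergence analysis is driven by
the deficit ramp alone — reproducing the qualitative field pattern of no
treatment separation during the rainy early window and a rapid deficit
decline from DAT 65.

Channel couplings, all monotone in s:

* green fraction `gf = 0.92·(1 − 0.35·s)`, greener fraction
  `ggf = gf·(0.85 − 0.45·s)` (so GGA ≤ GA always);
* canopy temperature placed *between the CWSI baselines*:
  `Tc = Ta + LL + s·(UL − LL)`, so a plot rendered at severity s recovers
  CWSI = s exactly under zero noise — the key closed-loop identity;
* bioristor level `R = R0·(1 − 0.75·s)` (multiplicative drought decay),
  modulated by a 24-h sinusoid (amplitude 0.12) plus additive exponential
  transients at rain/irrigation events (ΔR = 0.02 per mm, 6-h decay);
  currents are reconstructed as Ids = Ids0·(1 + R) with Ids0 = −10 µA,
  matching negative channel currents under Vds = −0.1 V;
* physiology: RWC = 95 − 25·s %, SPAD = 50 − 6·s.

Pixel-level rendering uses fixed vegetation/soil reflectance prototypes
(NIR 0.45 vs 0.25, red 0.05 vs 0.20 — NDVI 0.80 vs 0.11, a ≥ 0.3 NDVI
class separation) with Gaussian noise (default SD 0.02 reflectance;
thermal noise 7.5× that in °C so one knob scales both sensors).
Fractional pixel counts are tie-broken by deterministic raster-order fill,
which makes zero-noise index recovery exact up to one pixel quantum.

### Cross-channel coupling target

For pooled correlation studies the thermal and bioristor channels receive
independent Gaussian channel noise around the shared severity. Its SD is
derived analytically at generation time from the empirical severity
variance: corr = var(s)/(var(s)+v) = ρ ⇒ v = var(s)·(1−ρ)/ρ, with the
default target ρ = 0.8 (sign negative after the R decline). The bioristor
noise is held piecewise-constant between imaging dates so that daily
smoothing cannot average it away. The pipeline's pooled estimate then
lands near −0.8 (slightly attenuated by pixel/trace noise and CWSI
clipping), which is the property the acceptance suite checks with the
band [−0.9, −0.6].

### Yield

Per-treatment component means default to the reference field-trial values
(marketable 73/68.2/50.4, unripen 23.2/19.6/11.4, rotten 3.9/6.4/13.1
t/ha for 100/80/40% PAW); replicate SDs derive from the corresponding
experimental CVs (8.86/17.49/32.82%). Totals are computed as component
sums so additivity holds for every replicate. Three replicates per
treatment, matching the plot count.

## 2. Colour indices

Hue uses the arccos (geometric) HIS formulation with I = (R+G+B)/3 and
S = 1 − min/I. It agrees with hexcone HSV hue to within ~1.6° over the
saturation/value ranges the generator produces, and the generator keeps
hue blocks ≥ 4° away from the 60/80/180° thresholds, which absorbs both
that discrepancy and 8-bit quantization. Achromatic pixels have undefined
hue: they are excluded from the GA/GGA numerator but counted in the
denominator (a grey pixel is not green canopy). Hue intervals are closed
on both ends. No soil masking is applied before GA — these are
whole-image statistics, as in proximal canopy photography. CIELab/CIELuv
conversions use scikit-image (sRGB companding, D65 white point); the mean
hue reported per image is a circular mean over chromatic pixels.

## 3. Multispectral segmentation and extraction

Vegetation/soil segmentation is k-means with k = 2, k-means++
initialization, 10 restarts and a fixed seed, on per-feature
z-standardized pixel vectors (four bands, plus canopy temperature when a
thermal raster is supplied — on by default). The cluster with the higher
mean NDVI is labelled vegetation, which makes the mask invariant to
cluster-id permutations. On an all-vegetation scene both clusters are
high-NDVI and the mask covers the higher one — documented behaviour, not
an error. Nodata pixels never enter clustering or means. Plot geometries
are pixel-space half-open bounding boxes, 0-based, row-major; plots with
zero vegetation pixels yield missing means plus a warning.

## 4. CWSI

Saturation vapour pressure uses the Tetens form
es(T) = 0.6108·exp(17.27·T/(T+237.3)) kPa, the agrometeorology standard.
VPG reuses the baseline intercept as the temperature offset:
VPG = es(Ta) − es(Ta + a). The default baseline is a tomato-type
non-water-stressed line (a = 2.86 °C, b = −1.96 °C/kPa); alternatively
`fit_baseline_from_reference` estimates (a, b) by OLS of Tc − Ta on VPD
over the 100% PAW plots. The headline CWSI is clipped to [0, 1]; the raw
value is always retained for diagnostics because empirical baselines can
place observations outside the limits. Degenerate baselines (UL ≤ LL,
e.g. b = 0 or VPD = VPG) raise an error rather than returning 0/0.
Flight-time meteorology is the nearest record to noon of the imaging DAT
(tolerance 3 h, configurable).

## 5. Bioristor processing

R = |Ids − Ids0|/|Ids0| per sample. The absolute-value denominator keeps
R ≥ 0 for negative channel currents; the verbatim signed form is
available via `signed=True`. Smoothing is a 24-h centred moving average
followed by per-day means (one value per DAT, day boundary = calendar
day); min–max normalization maps onto [0, 1]. Three normalization scopes
exist: per-plant (default for trace plotting), per-treatment, and global.
The pooled correlation analysis uses the *global* scope — a single affine
map, hence Pearson-invariant — because per-plant min–max on a
near-constant well-watered trace would amplify pure noise to the full
[0, 1] range. Event detection is peak-prominence based
(`scipy.signal.find_peaks`); detected amplitudes are proportional to the
injected event intensity. Treatment divergence runs a one-way ANOVA per
day across treatments and reports the first DAT from which p ≤ 0.001
holds for three consecutive days (both configurable); days with globally
identical values give p = NaN, counted as non-significant.

## 6. Cross-scale statistics

Observation alignment outer-joins sources on (plot, nearest DAT within a
tolerance, default 0 days); duplicate keys or a variable supplied by two
sources are errors. Correlations are pairwise-complete Pearson (Spearman
by flag), pooled over treatments; cells with fewer than 3 complete pairs
are missing, never zero. Tukey HSD p-values come directly from the
studentized range distribution with the pooled MSE; the compact letter
display uses insert-and-absorb, with letters ordered by descending group
mean. statsmodels' `pairwise_tukeyhsd` serves as an independent
cross-check in the tests, never as the implementation. CV% is
100·√MSE/grand mean. No multiplicity correction is applied across the
correlation matrix.

With three replicates the printed yield letter pattern (100% and 80%
sharing a letter, 40% alone) is intrinsically stochastic: it requires a
within-group SD large enough to mask the 5.9 t/ha gap between the full
and mild treatments yet small enough to expose the ~18–23 t/ha deficit
gap. The acceptance script uses SD 4 t/ha — the geometric midpoint of the
two standardized effects — and reports the pattern *rate* over 100 seeded
tables (~78%) rather than a single seed-dependent flag.

## 7. Problem sizes and numerical choices

Plot patches are 24×24 pixels (rasters) and 48×48 (photos); the full
default trial is 9 plots × 9 dates plus 15 traces of 5,760 samples, which
keeps a complete pipeline run around a second while leaving every
statistic well-posed (81 pooled plot-dates, ≥ 0.3 NDVI class separation,
≥ 2 replicates everywhere). Ties in k-means are resolved by the fixed
seed; all generator randomness flows from one root seed through
deterministic child seeds, so identical configurations reproduce
byte-identical datasets and reports.

## 8. What the synthetic trial does and does not show

Passing tests demonstrate that the *computations* are correct and that
the pipeline recovers known couplings under realistic noise — not that
real tomato fields behave this way. The generator omits, among other
things: radiometric calibration error and orthomosaic artefacts, canopy
geometry/shadows in photos (hue classes are sampled independently per
pixel), soil heterogeneity, sensor drift and electrode degradation,
weather regimes beyond a clipped sinusoid with point rain events, and any
plant growth model beyond the prescribed index trajectories. Real-data
correlation magnitudes therefore cannot be inferred from the synthetic
ones; the synthetic targets only fix the sign structure and give the
estimator something known to recover.
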