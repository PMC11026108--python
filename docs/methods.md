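# Methods

`urbanveg` quantifies how urban and rural vegetation respond to extreme
hot months and what drives the difference. This note records the models,
the defaults and why, the numerical conventions, and what the synthetic
worlds do and do not establish.

## Hot-month events

A calendar month is *hot* when its mean temperature strictly exceeds the
in-sample 90th percentile of that calendar month across the record
(empirical quantile, linear interpolation between order statistics).
Maximal runs of hot months form events; events separated by fewer than 3
non-hot months are concatenated into one span (gap months included),
applied left-to-right. Events are characterized by

* **duration** — span length in months,
* **intensity** — mean exceedance of monthly mean temperature above the
  monthly climatological mean over the whole span (gap months included; a
  flagged-months-only intensity is kept as a secondary field),
* **season** — season of the start month (December starts count as DJF).

Detection runs on the city-average (urban + rural) temperature series per
ensemble member, so both areas are compared against the same city-scale
episodes; per-pixel detection is possible by passing per-pixel series.
Events are stratified at duration ≥ 4 months and intensity ≥ 2 °C
(both inclusive).

## Resistance and recovery

EVI is deseasonalized (per-calendar-month means removed) and *rebased* by
adding back the pixel long-term mean, preserving anomaly differences while
keeping a positive vegetation level in the denominator. With
EVI_pre = mean of the 3 months before the event, EVI_in = the in-event
value of maximum absolute change (earliest month on ties), and
EVI_post = mean of the 3 months after the event:

    resistance = 2 (EVI_in  − EVI_pre) / (EVI_pre + |EVI_in  − EVI_pre|)
    recovery   = 2 (EVI_post − EVI_pre) / (EVI_pre + |EVI_post − EVI_pre|)

Both metrics are zero at no change, signed like the change, and confined
to (−2, 2) for any positive baseline. Records are invalid when the pre
window is truncated by the record edge, the post window has fewer than 3
months, or EVI_pre ≤ 0; a following event starting inside the post window
sets an `overlap` flag but the value is still computed, so downstream
comparisons can filter either way. Pixels with ≥ 50% cropland cover or a
non-positive baseline are screened out before metric computation.

## Urban–rural comparison

Signs and magnitudes are compared separately, because a lower urban
median can mean fewer positive pixels or uniformly smaller magnitudes.
Each pool (pixels × events × ensemble members, per city/season/metric/
area) reports: fraction of positive values (exact zeros excluded from
numerator and denominator), median |value| over all / positive-only /
negative-only pixels, and median raw value. Deltas are urban minus rural.
Median ≠ 0 is tested with the two-sided Wilcoxon signed-rank test (exact
null for n ≤ 25, normal approximation above; all-zero input returns p = 1).
Pixels are treated as exchangeable — no spatial-autocorrelation
correction — matching common practice but understating significance where
responses are spatially coherent. No multiple-testing correction is
applied by default.

## Driver analyses

**City scale.** One row per (city, event, ensemble member), screened
within or across seasons. Non-land-cover predictors get Spearman
correlations (average ranks, two-sided p). Land-cover fractions are
compositional, so each type's correlation partials out the other six
types: ranks are OLS-residualized on the covariate ranks and the
residuals correlated (t-reference with n − 2 − k df); constant or
collinear covariates are dropped with a warning. GAMs use penalized cubic
B-splines (df = 6 per smooth, penalty α = 0.1; df = 5 cannot represent a
full oscillation), either one smooth per predictor or all seven
land-cover smooths jointly. Models are compared by in-sample R² and
AIC = n·log(RSS/n) + 2·edf with edf the total effective degrees of
freedom plus intercept; constants are dropped, so AICs are comparable
across models of the same response, and rescaling the response shifts all
AICs equally.

**Pixel scale.** Cities are grouped by dominant rural land-cover type
(argmax fraction; Crop-dominant cities excluded; ties break to the
canonical type order). Within a group, random forests (500 trees default,
√p features per split for sign classification, p/3 for magnitude
regression, fixed seed, OOB score reported) model the per-pixel response
sign (binary, zeros excluded) or magnitude (|metric|) from pixel-level
predictors. Per-predictor contributions use exact Saabas path
attribution: each split's change in the running mean prediction is
credited to the split feature; the reported contribution of a row is its
attribution minus that of the group's rural-centroid feature vector, so
contributions sum exactly to prediction(row) − prediction(baseline) and
positive values read "pushed the urban prediction above the rural
baseline". The rural centroid generally lies outside the urban training
support; this is inherent to the design and is why contributions are
interpreted jointly with partial dependence. Contribution significance is
the Spearman correlation between predictor and per-row contribution
(p ≤ 0.05, n ≥ 8). Partial-dependence grids span the 5th–95th percentile
of the predictor; the exact extremes are excluded because forcing a value
at an observed extreme routes all rows through noise-fit leaves.

### Predictors

Water-stress status: Spearman correlation of EVI anomalies with SPI and
with VPD over growing-season months (Apr–Oct) across all years; fewer
than 6 pairs or zero variance → missing. Optimal growth temperatures:
annual growing-season (temperature, EVI) pairs binned at 1 °C; the
optimum is the center of the bin with maximum mean EVI (< 3 occupied bins
→ missing; an edge-bin argmax is flagged as a boundary estimate).
Urban-heat-island intensity: mean of (pixel T − rural-mean T) over the
event plus 3 post months, for tmax and tmin. City rows carry
urban-minus-rural `*_diff` versions, the climatological seasonal mean
city temperature, event duration/intensity, urban impervious fraction and
rural land-cover fractions. SPI is consumed, not computed: the generator
supplies a standardized series, as Daymet-derived SPI would be supplied
in a real-data application.

## Synthetic city scenes

A scene is a grid with an urban disk, a rural ring, an impervious
fraction declining from the urban center, land-cover fraction maps
(either scaled by 1 − impervious or uniform), and an elevation field.
Monthly temperature = climatological cycle + shared AR(1) anomaly +
elevation lapse + urban-heat-island offset (urban pixels) + imposed event
exceedances. SPI is standardized AR(1) noise; VPD is lognormal around a
seasonal cycle with configurable correlation to the temperature anomaly.
EVI = seasonal cycle + concurrent gain a per °C of imposed exceedance −
delayed loss b·max(0, L−D0)·max(0, I−I0) spread uniformly over the 3
post-event months − water-stress coupling to SPI/VPD (suppressed for
irrigated urban pixels) + optional optimal-temperature curvature +
Gaussian noise, clipped to [0, 1] (clips counted). Urban response terms
are multiplied by a damping factor d ∈ (0, 1], optionally further reduced
in proportion to the pixel impervious fraction.

Key defaults and rationale:

| parameter | default | why |
|---|---|---|
| record length | 19 years × 12 months | length of the motivating 2001–2019 analyses |
| anomaly AR(1) φ, sd | 0.5, 0.8 °C | month-to-month persistence and spread typical of monthly mean-temperature anomalies |
| UHI offsets ΔTmax, ΔTmin | 1, 2 °C | nighttime-dominant heat island |
| concurrent gain a | 0.02 EVI/°C | a +2.5 °C event moves EVI by ~0.05, ≈ 15% of a 0.35 mean |
| delayed loss b, D0, I0 | 0.15, 4 mo, 2 °C | loss active only for long+intense events, total loss 0.025–0.1 EVI |
| EVI noise sd | 0.02 | with couplings 0.01 (SPI) and −0.03/kPa (VPD), growing-season EVI–moisture correlations land at ≈0.3–0.5, the moderate range reported for real greenness–moisture analyses |

The generator emulates: month-specific exceedance statistics (a
stationary scene flags ≈10% of each calendar month), urban damping,
irrigation decoupling, optimal-temperature contrasts, and land-cover
mosaics. It does **not** emulate: spatially correlated EVI noise,
phenological timing shifts, multi-year droughts, real moisture–
temperature covariance structure, or observation gaps. A green
parameter-recovery test therefore establishes that the estimators recover
what the generator put in — not that real cities behave this way.

Ensembles share climatology, events and static layers; anomaly and noise
realizations differ per member, standing in for multiple meteorological
data sources.

### Study designs (`urbanveg.cohort`)

* **Damping city** — one long, intense event per season, urban damping
  d = 0.5: the world in which urban magnitudes are smaller year-round.
* **Driver cohort** — 16 cities along a "westness" gradient: western
  cities are irrigated (urban EVI decoupled from VPD) and have higher
  urban optimal temperatures, and the same knobs carry the urban
  sign advantage; climate, UHI strength, impervious cover, land cover and
  event timing vary independently. SPI coupling is off so the
  water-stress pathway is identified through VPD (with both couplings on,
  the two correlation predictors are informationally identical).
  Elevation is wide and spatially unstructured (sd 250 m) so both areas
  sample a broad temperature range and the binned optimum is identifiable.
* **Attribution city** — uniform land cover, no irrigation or optimum
  offsets, reduced EVI noise, damping 1 − 0.9·impervious: a controlled
  experiment in which the impervious fraction is the only systematic
  driver of urban response variation. Events are staggered across the
  calendar: stacking several events in the same calendar months inflates
  the in-sample 90th-percentile threshold enough to unflag the events
  themselves.

Because detection runs on realized series, an imposed episode's detected
counterpart can start earlier or extend (spontaneous hot months
concatenate onto it); analyses conditioned on imposed events match
detected events by span overlap.

## Numerical conventions and degenerate inputs

Quantiles: linear interpolation between closest order statistics
throughout. Ties in "maximum change": earliest month. Sign convention:
exact zeros belong to neither sign class. Empty pools are emitted as
missing with n = 0; an all-pixel screen-out is legal and logged. All
randomness flows from `numpy.random.SeedSequence` spawns of a single
seed; reruns are byte-identical (CSV provenance headers carry the config
hash and seed, no timestamps).

## Limitations

Thresholds are in-sample (the record is its own baseline), so imposed
events slightly inflate their own thresholds; with staggered events the
effect is ≤ one order statistic. The pre-event window length (3 months)
mirrors the post window by design choice. City-scale screens with ~16
cities have limited power: spurious |rho| ≈ 0.3–0.5 is common, which is
why the driver-recovery checks are majority votes over seeds rather than
single-run assertions.
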