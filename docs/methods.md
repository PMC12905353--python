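# Methods

## Scope and design

The package reimplements, at desk scale, an empirical analysis of global
wildfire regimes: three GLMs of fire properties on sixteen gridded
predictors, an ignition-threshold procedure, anomaly-based scenario
construction with a factorial sensitivity design, and per-cell driver
attribution with biome aggregation. Every stage operates on synthetic
gridded data generated under known ground truth, so parameter recovery and
procedural identities are testable without external archives. The library
(`src/fireglm/`) holds all computation; `analysis/` contains thin numbered
drivers; the `fireglm` CLI orchestrates the same stages.

## Fire-property models

Burnt-area fraction is equated with a probability of burning and fitted as
a quasi-binomial GLM with logit link; fire size and fire intensity, which
are strongly overdispersed with many very small values, as quasi-Poisson
GLMs with log link. Model assumptions:

- mean structure is linear in the 16 predictors on the link scale (main
  effects only — no interaction or transformed terms);
- variance follows the quasi-family form `φ·V(μ)` with a free dispersion
  `φ` estimated as Pearson χ²/df; point estimates equal the plain-family
  MLE and standard errors scale by `√φ` (asserted as a property test);
- cells are treated as independent; no spatial-autocorrelation correction
  is applied to the standard errors.

Predictors are z-scored on the training cells (constants persisted with the
model) so that t = β/SE is unitless and comparable across predictors. FS
and FI responses are min-max normalised to [0, 1] before fitting, with the
constants stored for exact round-trip to physical units; normalisation is
global, not per-month. The burnt-area model is fitted on all cells; FS/FI
on observed-fire cells only, since those models describe fires that
occurred.

Fitting goes through statsmodels' IRLS with deviance tolerance 1e-8 and at
most 100 iterations. The Pearson dispersion is applied to the coefficient
covariance after the unit-scale fit rather than passed into the IRLS loop:
the estimates are identical and the iteration is numerically stabler on
degenerate (near-saturated) designs. Rank deficiency is detected before
fitting via the QR diagonal of the standardised design and reported with
the offending column names.

95% predictive confidence bands are `η ± 1.96·SE(η)` on the
linear-predictor scale, pushed through the inverse link — this keeps
burnt-area bounds inside (0, 1). A literal multiplicative variant
(`μ ± μ·1.96·SE`) is available behind the `literal` flag for comparison.

## Ignition threshold

The probabilistic burnt-area model never returns exactly zero, while the
FS/FI models return a value for every cell whether or not ignition is
possible. The threshold is a quantile (default the median,
linear-interpolation rule) of fitted burnt area on observed-zero cells;
cells with fitted BA below it have FS and FI set to zero. Skill is
summarised by TSS = sensitivity + specificity − 1, with predicted-positive
defined as fitted ≥ threshold (ties classify as burnable; the gate itself
uses strict <, consistent with that rule). The reported maxTSS column is
identically TSS + 1 (equivalently sensitivity + specificity). A
threshold-sensitivity harness repeats the FS/FI/unburnt-share summary at
the 25th/50th/75th percentiles.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
real geography:

- **Predictors**: independent Gaussian latents smoothed to an
  autocorrelation length of `spatial_scale` cells (default 3; scale 1 means
  white noise) and passed through fixed monotone transforms with realistic
  ranges — e.g. dry days ≤ 20 days, VPD lognormal around 1 kPa, population
  density heavy-tailed. Tree/grass/shrub/bare covers come from a
  four-component softmax so their sum never exceeds one.
- **Burnt area**: a mean-precision Beta draw around `expit(η_BA)` with
  `Var = φ_BA·μ(1−μ)` (default φ_BA = 0.01). This satisfies the
  quasi-binomial variance function exactly without truncation, which is
  what makes nominal CI coverage attainable; it was chosen over additive
  truncated noise for that reason.
- **Zero inflation**: the lowest `zero_fraction` (default 0.26) of latent
  burn probabilities are recorded as unburnt, mimicking the observed-zero
  mass the threshold procedure exploits — a censoring of the fire-prone
  tail, not an independent Bernoulli mask.
- **FS/FI**: gamma-mixed Poisson counts (`Var = φ·μ`, defaults φ = 3)
  around `exp(η)`, scaled to km² (0.1 km² per count) and W km⁻¹ (0.5 per
  count), giving medians near 2 km² and 25 W km⁻¹. FS = FI = 0 exactly
  wherever BA = 0.
- **Default coefficients** put the low tail of the burn-probability
  distribution near 10⁻³ with 26% unburnt cells — the regime in which the
  ignition threshold is meaningful — and were fixed once at design time.
- **Scenarios**: monthly seasonal cycles are constructed so that the
  climatology summary (mean dry days, range/mean seasonality, max-month
  VPD/DTR, hottest-month wind) reproduces the single-layer predictors
  exactly; per-member smooth biases cancel in the anomaly; requested shifts
  are additive, scaled 0.4× for the high-mitigation pathway; vegetation
  deltas are split into climate-driven and CO₂-driven components so the
  factorial isolation contract is exact; human layers are perturbed only
  when shifted, so held-constant experiments see bit-identical baselines.

What the generator does *not* emulate: real land/ocean geography, monthly
fire seasonality (the analysis operates on pre-summarised climatological
layers), cross-predictor spatial covariance of real climate, GCM-specific
change patterns, or fire–vegetation feedback. Passing tests therefore
demonstrate correctness of the procedures and estimators under the assumed
generative structure, not skill on real observations.

Because the latent-threshold zero inflation deliberately violates the GLM
mean model (it censors the least fire-prone cells), the parameter-recovery
and coverage studies run the generator with `zero_fraction = 0`; the
26%-zero regime is used where the zero mass is the object of study (the
threshold machinery).

## Scenario engine

Anomalies are additive for every variable (`future − piControl` per month,
added to the baseline climatology), with clip rules absorbing pathologies:
dry days to [0, days-in-month], fractions to [0, 1], VPD/wind/densities to
≥ 0. Clipping never moves an in-bounds value. Factor groups: climate =
{DD, DD_s, VPD, DTR, wind} plus climate-driven vegetation; CO₂ =
CO₂-driven vegetation; human = {popd, crop, roads}; VRM, TPI and lightning
are constant in all experiments. Cover deltas are capped so
tree + grass + shrub ≤ 1 by constraining only the modified layer. Road
density is projected by an OLS model on population density, GDP per capita
(total GDP / population count, with zero-population cells set to the grid
median and counted), OECD membership and cell area, clamped at zero; its
anomaly, not its raw prediction, perturbs the baseline roads layer. The
matrix is exactly 5 labels × 2 pathways × 4 members = 40 experiments with
unique keys.

## Attribution and aggregation

Contributions are computed on the standardised linear-predictor scale,
`Δηⱼ = Δzⱼ·βⱼ`, where `Σⱼ Δηⱼ ≡ Δη` holds to machine precision;
response-scale effects are reported separately as predicted-property
differences. Dominant-driver ties break to the lowest predictor index in
canonical order, and exact-zero contributions never win. Biome aggregation
uses spherical-zone cell areas (a full global grid closes on the Earth's
surface area to < 1%); global percentages are taken against the sum of the
aggregated rows. Change maps use relative change with the modern value as
denominator (> 5% by default); modern-zero cells are excluded and counted,
not mapped to infinity. The tropics boundary defaults to ±23.5° latitude
and is configurable.

## Problem sizes and numerical choices

- Default grid: 40 × 20 cells at 0.5° in a 40–50°N band — large enough for
  stable 17-parameter GLM fits in well under a second.
- Recovery studies: 100 × 50 cells (n = 5000), 50 replicates for slope bias
  and CI coverage, 10 per response for dispersion recovery.
- Quantile rule: linear interpolation between order statistics everywhere.
- Seeds: every stochastic stage takes an explicit seed; derived seeds are
  small fixed offsets so a config re-runs bit-identically (the run manifest
  records SHA-256 hashes of all artifacts, and a repeated run reproduces
  them).
- fAPAR rescaling clips to 1 − 10⁻⁹ to preserve the open interval of the
  Beer–Lambert form; Eq. for combined GPP uses the C4 product in the C4
  term (convex combination).

## Known limitations

- The ignition-threshold structure in the synthetic world is close to
  separable (zero cells are exactly the least fire-prone), so TSS values
  run higher than on real observations, where fitted and observed zeros
  overlap more.
- Quasi-family standard errors ignore residual spatial correlation; on
  strongly smoothed fields CI coverage will be optimistic.
- Min-max normalisation of FS/FI makes the log-link mean model inexact
  through the min-shift; with the observed minima near zero the induced
  slope bias is negligible at the default settings, but it is a property of
  the normalisation, not of the estimator.
- One socioeconomic pathway; no lightning projections; no fire–vegetation
  feedback; map rendering is out of scope.
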