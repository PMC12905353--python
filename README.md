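# fireglm

Empirical generalised-linear-model (GLM) pipeline for global wildfire
regimes: how burnt area, fire size and fire intensity respond to climate,
vegetation, CO₂ and human activity, and how those responses project onto
end-of-century scenarios. It is aimed at fire ecologists and global-change
modellers who want a tested, desk-scale implementation of the
space-for-time GLM approach — from predictor synthesis to per-cell driver
attribution — without the multi-GB gridded archives the full-scale analysis
consumes. A synthetic-data generator with known ground truth stands in for
the observations, so every stage runs and is verified in seconds.

## The models

Three fire properties are modelled per 0.5° grid cell on a common set of 16
standardised predictors `x` (dry days DD and their seasonality DD_s, VPD,
DTR, wind, GPP and its seasonality, grass/shrub/tree cover, population
density, cropland, road density, VRM, TPI, lightning):

- **Burnt area** `BA ∈ [0, 1]`, read as a probability of burning —
  quasi-binomial, logit link: `logit(μ) = β₀ + βᵀx`,
  `Var(y) = φ·μ(1−μ)`.
- **Fire size** FS (monthly median, km²) and **fire intensity**
  FI (median FRP/√FS, W km⁻¹) — quasi-Poisson, log link on min-max
  normalised responses: `log(μ) = β₀ + βᵀx`, `Var(y) = φ·μ`.

Dispersion `φ` is the Pearson χ²/df; predictor importance is ranked by
|t| = |β|/SE on the z-scored scale. Because the burnt-area model is
probabilistic its fitted values never reach zero, so an **ignition
threshold** — the median fitted BA on observed-zero cells — gates FS and FI
to zero where burning is not expected, and is evaluated as a
presence/absence classifier with the True Skill Statistic
(TSS = sensitivity + specificity − 1).

Future forcings are built by the **anomaly (delta) method**
(`baseline + (future − piControl)` per climate-model member) and crossed in
a factorial design: {realistic, climate-only, CO₂-only, climate+CO₂,
human-only} × {RCP2.6-like, RCP6.0-like} × 4 members = 40 experiments.
Changes are attributed per cell to individual predictors by the first-order
decomposition `Δηⱼ = Δxⱼ·βⱼ` on the linear-predictor scale, which sums
exactly to the total change in η, and burnt area is aggregated to biomes as
area-weighted km² totals.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`. For instance:

```bash
python analysis/04_ignition_threshold.py
```

prints

```
observed-zero cells: 208 (26.0%)
median-threshold: 0.000713 (sensitivity 1.000, specificity 0.500, TSS 0.500)
TSS-optimal percentile 0.9: threshold 0.002241, TSS 0.899
```

i.e. about a quarter of cells are observed unburnt, the median fitted
burnt-area fraction on those cells (≈7×10⁻⁴) becomes the ignition gate, and
the TSS sweep across percentiles lands where sensitivity and specificity
balance. `analysis/06_attribute_and_report.py` then projects all 40
experiments and reports, for this synthetic world,

```
rcp26: above-threshold cells change +2.0% (18 gained, 4 lost)
rcp60: above-threshold cells change +7.8% (54 gained, 0 lost)
rcp26: global burnt area change +16.1% (realistic ensemble mean)
rcp60: global burnt area change +74.9% (realistic ensemble mean)
```

— burnable area expands and burnt area grows much faster under the
low-mitigation pathway, with the biome-level breakdown in
`results/biome_table_rcp60.csv` and the dominant drivers per property in
`results/drivers_*_*.csv`.

The same workflow is available as a CLI
(`fireglm run --seed 42 --out runs/demo`, with `simulate`, `fit`,
`threshold`, `project` and `report` subcommands for individual stages) or
programmatically:

```python
import fireglm as fg

ds = fg.generate_dataset(seed=42)
model = fg.fit_glm(ds.predictors, ds.fire.BA.ravel(), "BA")
report = fg.derive_threshold(fg.predict(model, ds.predictors).ravel(),
                             ds.fire.BA.ravel())
print(report.threshold, report.TSS)
```

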