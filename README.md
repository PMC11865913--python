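# aphidscape

Tools for analyzing the field dynamics of the sorghum aphid (*Melanaphis
sorghi*) and its natural enemies — predatory lady beetles and parasitoid
wasps (observed as aphid "mummies") — in the context of the surrounding
agricultural landscape and local weather.

The package is aimed at agroecologists and biocontrol researchers who sample
per-leaf insect counts from crop fields through a season and want to relate
summary statistics of those population dynamics to landscape composition,
landscape configuration, and weather covariates.

## What it computes

**Insect population-dynamics metrics** per field-year, from a time series of
per-leaf counts of sorghum aphids (SA), lady beetles (LB), and mummies (MM):

| metric | definition |
|---|---|
| nSAmax, nLBmax, nMMmax | maximum per-leaf count of each group |
| rLBMMmax | nLBmax / nMMmax |
| dtSAmax | days from the last zero-aphid sampling event to the aphid maximum |
| dtRespLB, dtRespMM | enemy first-appearance day (after absence) minus the aphid first-appearance day |
| vSA, vLB, vMM | each group's maximum divided by its own zero-to-maximum interval (per leaf per day) |

Metrics whose reference events do not exist (e.g. a series that starts with
aphids already present) are missing, and nSAmax, nLBmax, nMMmax, dtRespLB and
dtRespMM are retained downstream only when strictly positive.

**Landscape metrics** within a circular buffer (default radius 5 km) on a
categorical land-cover raster, in the FRAGSTATS nomenclature: PLAND (percent
of landscape), PD (patch density per 100 ha), ED (edge density, m/ha),
SHAPE_MD (median shape index), CLUMPY (clumpiness, in [−1, 1]), PROX_MD
(median proximity index), and the landscape-level Simpson diversity and
evenness indices SIDI and SIEI.

**Weather metrics** over each site's sampling window: maxTMAX, sdTMAX (°C),
meanPPT (mm), cvPPT (sd/mean; undefined for rain-free windows).

**The statistical chain**, per insect metric *y*:

1. year pooling — one-way ANOVA on ranks across years, followed (when
   significant at α = 0.05) by Tukey HSD on the same ranks; the largest
   mutually non-significant set of years is pooled;
2. natural-log transform of the seven right-skewed metrics
   (nSAmax, nLBmax, nMMmax, rLBMMmax, vSA, vLB, vMM);
3. an iterative variance-inflation-factor screen of the candidate
   covariates (drop the largest VIF above the threshold, recompute);
4. exhaustive best-subset OLS: all 2^k covariate subsets ranked by

   AICc = n ln(RSS/n) + n(1 + ln 2π) + 2p + 2p(p+1)/(n − p − 1),

   with p counting the coefficients, intercept, and residual variance.
   The AICc minimum is the optimal model; models within ΔAICc < 2 form the
   top set, over which per-covariate inclusion frequencies are reported.

The selection engine is exposed as sklearn-compatible estimators
(`ExhaustiveAICcRegressor`, `VIFScreen`) that work in sklearn pipelines.

A **synthetic agroecosystem generator** produces land-cover rasters with
controllable composition and patch aggregation, daily weather, and insect
sampling series from a discrete-time predator–prey–parasitoid model with
known ground truth, so the entire chain is testable without field data.

## Worked example

Run the full chain on the bundled demonstration study (20 fields × 2 years,
in which the generator injects a known positive effect of sorghum cover,
PLANDs, on the aphid carrying capacity):

```sh
aphidscape run-all --config configs/demo.yaml --seed 7 --out demo_out
```

`demo_out/optimal_models.csv` then contains, among others:

```
        dependent  variable  coefficient  p_coefficient     r2  adj_r2  p_model   n
ln(nSAmax) [2018] Intercept       4.4695         0.0000 0.2972  0.2582   0.0129  20
ln(nSAmax) [2018]    PLANDs       0.0672         0.0129 0.2972  0.2582   0.0129  20
          ln(vSA) Intercept       1.8874         0.0000 0.2627  0.2012   0.0111  40
          ln(vSA)    PLANDs       0.0464         0.0173 0.2627  0.2012   0.0111  40
          ln(vSA)   PLANDwh      -0.0124         0.0770 0.2627  0.2012   0.0111  40
          ln(vSA)    PLANDc      -0.0503         0.0532 0.2627  0.2012   0.0111  40
```

The injected sorghum-cover effect is recovered: PLANDs enters the optimal
models for the aphid maximum and the aphid speed of increase with a positive
coefficient. `inclusion_frequencies.csv` shows PLANDs present in all six
ΔAICc < 2 models for ln(vSA) (frequency 1.00) while the weather covariates,
which carry no injected effect, appear in none.

The other outputs are `anova_pooling.csv` (per-metric ANOVA p, Tukey p's and
the pooled year set), `vif_report.csv` (per-round VIF values and removals),
`spearman.csv` (metric correlation matrix), the intermediate metric tables,
and `run_manifest.json` with the config hash and file checksums; rerunning
with the same seed reproduces every CSV byte for byte.

Stage-wise commands (`simulate`, `landmetrics`, `field-metrics`, `fit`)
operate on the same file schemas, so each stage can be run on user data.

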