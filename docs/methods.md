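# Methods

This note records the models, conventions, and design decisions behind
`aphidscape`, in the order the pipeline runs.

## Insect population-dynamics metrics

A sampling series is an ordered list of events (day of year, leaves
examined, totals of aphids, lady beetles, mummies); per-leaf values are
totals divided by leaves, carried as reals. Two anchor events drive the
derived metrics:

* the **first appearance after absence** of a group: the earliest event with
  a positive count immediately preceded by an event with a zero count;
* the **last-zero anchor**: the last zero event preceding the group's first
  positive event.

dtSAmax runs from the aphid last-zero anchor to the first event attaining
the aphid maximum (first event, when the maximum ties). The speeds vSA, vLB,
vMM divide each group's maximum by its own last-zero-to-maximum interval, so
vSA × dtSAmax = nSAmax exactly whenever all three exist. The last-zero
anchoring was chosen because the speed definitions make it explicit; the
time-to-maximum definition is kept consistent with them.

Missingness is structural, not imputed: a series that starts with a group
already present has no anchor, so the metrics needing it are missing. The
retention rule keeps nSAmax, nLBmax, nMMmax, dtRespLB and dtRespMM for
modeling only when strictly positive; response times ≤ 0 (an enemy appearing
on or before the aphid reference day) are computed and reported but flagged
out. A zero always means "sampled and none observed"; unsampled days carry
no information.

## Landscape metrics

Conventions, each pinned by an oracle test:

* **Buffer membership**: a pixel belongs to the buffer iff its center lies
  within the radius (default 5000 m); area = pixel count × pixel area.
* **Landscape area**: in-buffer pixels excluding the background category.
  PLAND, PD, ED, SIDI and SIEI are computed over this area, so PLAND sums to
  100 over the non-background classes in any buffer.
* **Connectivity**: patches are 8-connected by default (the common raster
  default), configurable to 4.
* **Perimeter**: pixel sides between a class pixel and a different class
  count; sides facing out-of-buffer or off the raster also count by default
  (`count_boundary=False` disables that).
* **SHAPE**: 0.25 × perimeter / (resolution × √pixels), floored at 1 (the
  value of a square patch); the median over patches is reported.
* **CLUMPY**: the like-adjacency proportion G is tallied over ordered
  side-adjacent pairs of in-buffer, non-background pixels whose first member
  is the focal class (double-count convention: a like pair contributes two
  ordered pairs, an unlike pair one). CLUMPY = (G − P)/(1 − P) for G ≥ P,
  else (G − P)/P, with P the focal class's share of the landscape. No
  small-class perimeter correction is applied — with it, the G of a class
  filling the buffer exceeds 1 and the CLUMPY = 1 limit breaks; a class
  filling the landscape returns 1 by convention.
* **PROX**: between-patch distance is the minimum cell-center to cell-center
  distance. The search radius has no natural default in a 5-km buffer; the
  package default is 1000 m and the configuration makes it explicit. PROX
  values grow roughly with (patch area)/(distance²), so halving the radius
  zeroes the contribution of neighbors between the radii but never changes
  the contributions of nearer neighbors.
* **SIDI/SIEI**: proportions are renormalized over the non-background
  classes present; SIEI = SIDI/(1 − 1/m) needs m ≥ 2 classes and is missing
  otherwise.

Redundancy pruning clusters metrics whose pairwise |Spearman r| reaches a
threshold (default 0.7) and keeps one configured representative per cluster
(defaults: PD among the focal-crop configuration metrics, SIDI among the
diversity metrics).

## Weather metrics

Site values interpolate bilinearly from the four surrounding cell centers of
a gridded daily product. Over each site's sampling window: maxTMAX, sdTMAX,
meanPPT, cvPPT. Standard deviations and the coefficient of variation use the
sample (n − 1) convention. cvPPT is undefined when meanPPT = 0; records with
undefined cvPPT are removed before the pooling ANOVA for any dependent
variable whose candidate set includes cvPPT.

## Year pooling

Per metric: one-way fixed-effects ANOVA on jointly midranked values across
years. If non-significant at α (default 0.05), all years pool. Otherwise
Tukey HSD (studentized range with the Tukey–Kramer unequal-n correction) is
applied to the same ranks, and the pooled set is the largest set of years
that are pairwise non-significant, ties broken by the largest minimum
pairwise p, then by earliest years. Running Tukey on the ranks (rather than
the raw values) keeps the post-hoc consistent with the rank ANOVA that
triggered it; the two scales give the same qualitative decisions on the
published p-value patterns the tests reproduce. Years outside the pooled set
are dropped by default; `unpooled_policy: separate` instead fits each
leftover year on its own (used by the demo, which has only two seasons).

## Regression and model selection

The seven right-skewed metrics are ln-transformed (a heteroscedasticity
check is reported, never silently applied); dtSAmax, dtRespLB and dtRespMM
stay on the raw scale. Candidates are screened by iterated VIF (drop the
largest VIF above the threshold, default 10, recompute until all pass);
perfectly collinear candidates surface as unbounded VIFs and go first.

The selection engine fits every subset of the surviving candidates with OLS
(intercept always present) and ranks by AICc with the parameter count
p = k + 2 (k slopes, intercept, residual variance) — the dominant convention
for regression AICc; the arithmetic is pinned by a test so an alternative
convention is a one-line change. Enumeration solves each subset's normal
equations on a centered, standardized Gram matrix (RSS is invariant to these
affine changes of basis when an intercept is present); the optimal model and
the ΔAICc < 2 top set are refitted fully for coefficients, standard errors
and t-tests. Subsets with n − p − 1 ≤ 0 or rank-deficient designs are
skipped and recorded rather than given infinite AICc. Equal-AICc ties rank
the smaller model first, then lexicographic variable order, so outputs are
deterministic.

**Post-selection inference caveat.** The F-test of the AICc-optimal model is
not calibrated: selection picks models that fit the realized noise, so on
effect-free data its significance rate is far above the nominal level (the
null experiment measures roughly 55% at α = 0.05). The chain therefore also
reports the *full* (pre-selection) model's F p-value, whose null rate tracks
the nominal 5% and is what the calibration test asserts. Inclusion
frequencies over the top set are reported as descriptive weights, never as
averaged coefficients.

## Synthetic agroecosystem

The generator exists so every stage has known ground truth; it emulates the
sampling design of a multi-year aphid field study (weekly sampling, ~100
leaves per event, 5-km landscape buffers) without claiming realism beyond
what the tests need.

* **Landscapes.** Each class's pixel quota (target proportion × grid size)
  is carved from a Gaussian-smoothed white-noise score field, largest quota
  first; unassigned pixels are background. Composition is exact to rounding
  by construction. The smoothing length grows with `aggregation_level`
  (σ = 0.5 + level × 0.06 × grid side), so level 0 gives salt-and-pepper
  scatter (many single-pixel patches, low CLUMPY) and level 1 a few large
  blobs (high CLUMPY); patch count falls and clumpiness rises monotonically
  in expectation, which the tests check by rank correlation. Per-site
  lognormal jitter (sd 0.4) on the class mix makes covariates vary across
  fields.
* **Weather.** Daily TMAX ~ Normal around a site mean that declines
  northward (−4 °C per 100 km by default, mean 33 °C, sd 3 °C); PPT is
  zero-inflated Gamma (wet-day probability 0.25, shape 0.8, scale 10 mm,
  with a northward scale gradient). Values emulate a warm-temperate sorghum
  season. There is no spatial correlation between sites and no seasonality
  within the window — deliberately outside scope.
* **Insect dynamics.** Daily latent per-leaf densities: logistic aphid
  growth (r₀ = 0.28 day⁻¹, K₀ = 150 leaf⁻¹) suppressed by mass-action
  predation from lady beetles (attack 0.08) and parasitism pressure from
  mummies (0.02); enemies recruit in proportion to the aphid density lagged
  by 10 (beetles) and 14 (mummies) days and decay at 0.10/0.08 per day.
  Aphids arrive at a uniform random day 7–28 days after sampling starts, so
  series open with all-zero events and the first-appearance anchors exist
  (`start_mid_outbreak` starts sampling after arrival to exercise the
  missing-metric paths). Covariates act through
  ln r = ln r₀ + Σ βⱼ(xⱼ − cⱼ) and likewise for ln K, plus lognormal
  field noise (sd 0.15 and 0.30). Observed totals are negative-binomial
  (Gamma–Poisson) with mean = latent density × leaves and shape 10 —
  overdispersed relative to Poisson by a factor ≈ 1 + mean/10.
* **What it does not emulate:** within-field spatial structure (fields are
  well-mixed), plant phenology, management events, spatially correlated
  weather, inter-annual trends. Passing tests therefore demonstrate the
  correctness of the estimators and the internal consistency of the chain on
  data with these properties, not the field realism of any fitted value.

## Calibration and recovery experiments

* **Rank-ANOVA null**: 500 replicates of 3 × 20 standard-normal groups;
  the rejection rate at α = 0.05 is asserted within [0.03, 0.07].
* **Chain null**: one 25-site × 2-year study's landscapes and weather are
  generated once; 200 replicates redraw insect series with no covariate
  effects and rerun the chain (seven-candidate sets per metric). The
  full-model F significance rate is asserted within [0.02, 0.09] — the
  nominal 5% widened to a three-sigma binomial band.
* **Recovery**: responses y = 0.5 + 0.13·PLANDs + 0.40·meanPPT + N(0, 1) at
  n = 141 (the largest per-metric sample in the motivating study design),
  with PLANDs lognormal around 4% and meanPPT Gamma, plus three pure-noise
  covariates. The effect sizes give partial t ≈ 6 — clearly detectable by
  design, since the experiment probes interval calibration and selection
  behavior, not power. Over 300 replicates the full-model 95% CI for the
  PLANDs effect must cover the truth in [0.90, 0.98] of replicates, and the
  true predictors' mean inclusion frequency in the ΔAICc < 2 set must exceed
  the noise predictors' in ≥ 90% (a single noise covariate can tie at
  frequency 1.0 when the top set is tiny, so the aggregate comparison is the
  stable statement of the property).

Problem sizes throughout (grid sizes, site counts, replicate counts) are
chosen so the full suite and the acceptance script each run in a few minutes
on one CPU while keeping binomial error bands tight enough to be meaningful.

## File formats

Rasters use a plain-text grid dialect (`ncols/nrows/cellsize/xllcorner/
yllcorner` header, then space-separated integer codes, row 0 at the top);
coordinates are planar meters, origin at the lower-left corner, pixel-center
convention. Tables are UTF-8 CSV with `.` decimals, ISO dates, and empty
fields for missing values. Every run writes `run_manifest.json` with the
config hash, seed, package version and SHA-256 checksums of all outputs;
identical configuration and seed reproduce every CSV byte for byte.

## Known limitations

* Landscape metrics beyond the implemented list (e.g. core-area or
  contagion families) are out of scope, as are vector land cover and map
  reprojection — inputs are assumed planar.
* The regression chain fits fixed-effects OLS only: no mixed effects, no
  spatial autocorrelation, no coefficient model-averaging.
* PROX and CLUMPY conventions vary between raster packages; the conventions
  above are internally consistent and oracle-pinned but may differ in the
  last decimals from other implementations.
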