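# Demonstration study: 20 fields followed for two seasons.
# The 90 m raster resolution keeps the demo fast while leaving >100 pixels
# across each 5-km buffer.
simulation:
  seed: 7
  n_sites: 20
  years: [2017, 2018]
  raster_resolution: 90.0
  aggregation_level: 0.5
  dynamics_params:
    # known ground truth: sorghum cover raises the aphid carrying capacity
    beta_lnK:
      PLANDs: 0.06
    covariate_centers:
      PLANDs: 4.0
landscape:
  radius: 5000.0
  connectivity: 8
  prox_radius: 1000.0
pipeline:
  alpha: 0.05
  vif_threshold: 10.0
  delta_aicc: 2.0
  min_n: 10
  # with only two seasons, analyze unpoolable years separately rather than
  # dropping the metric
  unpooled_policy: separate
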