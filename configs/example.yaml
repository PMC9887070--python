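# Example run configuration for `apcmap all --config configs/example.yaml`.
# With no `inputs`, the pipeline simulates the default synthetic scenario
# first and feeds its own outputs forward.
seed: 1
outdir: apcmap_out
# inputs:
#   incidence: data/incidence.csv        # sex,histology|morphology,area_id,year,age_group,count
#   person_years: data/person_years.csv  # sex,area_id,year,age_group,person_years
#   geometry: data/areas.geojson         # FeatureCollection with an area_id property
age_range: [30, 84]
band_width: 5
apc_period_range: [1997, 2016]
reference_window: null        # default: last five data years
strata: null                  # default: every (sex, histology) present
aapc:
  max_joinpoints: 2
  area_max_joinpoints: 1
  interval: null              # e.g. [1997, 2007] for a sub-interval analysis
kriging:
  resolution: 1.0
  n_bins: 12
  model: exponential          # or spherical
  tolerance: 0.05             # near-null band half-width
  error_mode: post_shrinkage  # or raw
  sir_contours: [0.8, 0.9, 1.0, 1.1, 1.25]
  aapc_contours: [-2, -1, 0, 1, 2]
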