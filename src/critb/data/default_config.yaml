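# Default assessment configuration.
lqh:
  # land-use classes counted as anthropogenic disturbance (low-quality habitat)
  anthropogenic_codes: [bare, crop, urban, water]
  # threat-influence dilation around disturbed cells, km
  buffer_km: 2.0
  # severe fragmentation when RA_LQH strictly exceeds this percentage
  severe_threshold_percent: 50.0
  # patch adjacency rule: 8 (queen) or 4 (rook)
  connectivity: 8
locations:
  # villages must have population strictly greater than this to count as threats
  min_population: 100
  # radius of the locality disk around each village, km
  locality_radius_km: 2.5
# restricted-distribution screens (strict "smaller than")
eoo_restricted_km2: 20000.0
aoo_restricted_km2: 2000.0
# AOO overlay grid cell, km (IUCN standard 2x2 km)
aoo_cell_km: 2.0
# SDM: background resample replicates and L2 regularization
n_replicates: 10
n_background: null
regularization: 1.0
seed: 0
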