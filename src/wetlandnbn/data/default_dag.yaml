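# Default metamodel: wetland traits -> alpha avian diversity.
# Arc order is significant: for each child it fixes the conditioning order
# of the arc partial correlations.
nodes:
  - size
  - isolation
  - distance_to_coastline
  - tourism_pressure
  - anthropization
  - mean_water_level
  - water_level_fluctuations
  - water_salinity
  - water_discharges
  - water_diversions
  - alpha_diversity
sink: alpha_diversity
arcs:
  # anthropic pressure drives the hydrological disturbances
  - [anthropization, water_discharges, "+"]
  - [anthropization, water_diversions, "+"]
  # proximity to the sea raises tourism pressure and saltwater intrusion
  - [distance_to_coastline, tourism_pressure, "-"]
  - [distance_to_coastline, water_salinity, "-"]
  # discharges raise, diversions depress, the water-level regime
  - [water_discharges, mean_water_level, "+"]
  - [water_discharges, water_level_fluctuations, "+"]
  - [water_diversions, mean_water_level, "-"]
  - [water_diversions, water_level_fluctuations, "-"]
  # direct influences on alpha diversity
  - [size, alpha_diversity, "+"]
  - [water_level_fluctuations, alpha_diversity, "+"]
  - [isolation, alpha_diversity, "-"]
  - [mean_water_level, alpha_diversity, "+"]
  - [water_discharges, alpha_diversity, "-"]
  - [water_salinity, alpha_diversity, "-"]
  - [anthropization, alpha_diversity, "-"]
  - [tourism_pressure, alpha_diversity, "-"]
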