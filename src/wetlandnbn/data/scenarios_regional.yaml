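# Regional what-if scenarios for the Sicilian coastal wetlands.
# S_0 is the unconditioned baseline; S_1..S_7 worst-case, S_8..S_14
# management (best-case), S_15..S_20 mixed.  Ordinal levels: 0 = absent,
# 1 = localized, 2 = scattered, 3 = widespread.  Water level fluctuations
# are in cm.
scope: regional
scenarios:
  - id: S_0
    description: baseline (no conditionalization)
    evidence: {}
  - id: S_1
    description: tourism pressure widespread in all wetlands
    evidence: {tourism_pressure: 3}
  - id: S_2
    description: water salinity widespread in all wetlands
    evidence: {water_salinity: 3}
  - id: S_3
    description: water discharges null in all wetlands
    evidence: {water_discharges: 0}
  - id: S_4
    description: anthropization widespread in all wetlands
    evidence: {anthropization: 3}
  - id: S_5
    description: water diversions widespread in all wetlands
    evidence: {water_diversions: 3}
  - id: S_6
    description: water level fluctuations null in all wetlands
    evidence: {water_level_fluctuations: 0}
  - id: S_7
    description: worst possible scenario (S_1..S_6 together)
    evidence:
      tourism_pressure: 3
      water_salinity: 3
      water_discharges: 0
      anthropization: 3
      water_diversions: 3
      water_level_fluctuations: 0
  - id: S_8
    description: tourism pressure null in all wetlands
    evidence: {tourism_pressure: 0}
  - id: S_9
    description: water salinity null in all wetlands
    evidence: {water_salinity: 0}
  - id: S_10
    description: water discharges widespread in all wetlands
    evidence: {water_discharges: 3}
  - id: S_11
    description: anthropization null in all wetlands
    evidence: {anthropization: 0}
  - id: S_12
    description: water diversions null in all wetlands
    evidence: {water_diversions: 0}
  - id: S_13
    description: water level fluctuations 30 cm in all wetlands
    evidence: {water_level_fluctuations: 30}
  - id: S_14
    description: best possible scenario (S_8..S_13 together)
    evidence:
      tourism_pressure: 0
      water_salinity: 0
      water_discharges: 3
      anthropization: 0
      water_diversions: 0
      water_level_fluctuations: 30
  - id: S_15
    description: all conditions deteriorate but tourism pressure is null
    evidence:
      tourism_pressure: 0
      water_salinity: 3
      water_discharges: 0
      anthropization: 3
      water_diversions: 3
      water_level_fluctuations: 0
  - id: S_16
    description: all conditions deteriorate but water salinity is null
    evidence:
      tourism_pressure: 3
      water_salinity: 0
      water_discharges: 0
      anthropization: 3
      water_diversions: 3
      water_level_fluctuations: 0
  - id: S_17
    description: all conditions deteriorate but water discharges are widespread
    evidence:
      tourism_pressure: 3
      water_salinity: 3
      water_discharges: 3
      anthropization: 3
      water_diversions: 3
      water_level_fluctuations: 0
  - id: S_18
    description: all conditions deteriorate but anthropization is null
    evidence:
      tourism_pressure: 3
      water_salinity: 3
      water_discharges: 0
      anthropization: 0
      water_diversions: 3
      water_level_fluctuations: 0
  - id: S_19
    description: all conditions deteriorate but water diversions are null
    evidence:
      tourism_pressure: 3
      water_salinity: 3
      water_discharges: 0
      anthropization: 3
      water_diversions: 0
      water_level_fluctuations: 0
  - id: S_20
    description: all conditions deteriorate but water level fluctuations equal 30 cm
    evidence:
      tourism_pressure: 3
      water_salinity: 3
      water_discharges: 0
      anthropization: 3
      water_diversions: 3
      water_level_fluctuations: 30
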