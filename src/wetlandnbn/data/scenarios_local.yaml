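# Local (single-wetland) what-if scenarios, downscaled to the Pantano Bruno
# wetland.  Every scenario conditions the five baseline traits below at the
# wetland's 2016 values, with the scenario's evidence overriding a subset.
# S_21..S_33 worst-case, S_34..S_45 best-case, S_46..S_50 mixed.
scope: local
baseline_evidence:
  water_level_fluctuations: 6.8
  water_salinity: 0
  water_diversions: 2
  water_discharges: 2
  tourism_pressure: 1
scenarios:
  - id: S_0
    description: Pantano Bruno baseline (2016 trait values)
    evidence: {}
  - id: S_21
    description: increase in water salinity
    evidence: {water_salinity: 3}
  - id: S_22
    description: increase in tourism pressure
    evidence: {tourism_pressure: 3}
  - id: S_23
    description: decrease in water discharges
    evidence: {water_discharges: 0}
  - id: S_24
    description: increase in water diversions
    evidence: {water_diversions: 3}
  - id: S_25
    description: water level fluctuations = 5 cm
    evidence: {water_level_fluctuations: 5.0}
  - id: S_26
    description: water level fluctuations = 0 cm
    evidence: {water_level_fluctuations: 0.0}
  - id: S_27
    description: S_21 and S_22 together
    evidence: {water_salinity: 3, tourism_pressure: 3}
  - id: S_28
    description: S_21 and S_23 together
    evidence: {water_salinity: 3, water_discharges: 0}
  - id: S_29
    description: S_21 and S_24 together
    evidence: {water_salinity: 3, water_diversions: 3}
  - id: S_30
    description: S_21 and S_25 together
    evidence: {water_salinity: 3, water_level_fluctuations: 5.0}
  - id: S_31
    description: S_21 and S_26 together
    evidence: {water_salinity: 3, water_level_fluctuations: 0.0}
  - id: S_32
    description: S_21, S_23 and S_25 together
    evidence: {water_salinity: 3, water_discharges: 0, water_level_fluctuations: 5.0}
  - id: S_33
    description: worst possible scenario
    evidence:
      water_level_fluctuations: 0.0
      water_salinity: 3
      water_diversions: 3
      water_discharges: 0
      tourism_pressure: 3
  - id: S_34
    description: decrease in tourism pressure
    evidence: {tourism_pressure: 0}
  - id: S_35
    description: increase in water discharges
    evidence: {water_discharges: 3}
  - id: S_36
    description: decrease in water diversions
    evidence: {water_diversions: 0}
  - id: S_37
    description: water level fluctuations = 10 cm
    evidence: {water_level_fluctuations: 10.0}
  - id: S_38
    description: water level fluctuations = 15 cm
    evidence: {water_level_fluctuations: 15.0}
  - id: S_39
    description: water level fluctuations = 20 cm
    evidence: {water_level_fluctuations: 20.0}
  - id: S_40
    description: water level fluctuations = 25 cm
    evidence: {water_level_fluctuations: 25.0}
  - id: S_41
    description: water level fluctuations = 30 cm
    evidence: {water_level_fluctuations: 30.0}
  - id: S_42
    description: S_35 and S_37 together
    evidence: {water_discharges: 3, water_level_fluctuations: 10.0}
  - id: S_43
    description: S_35 and S_41 together
    evidence: {water_discharges: 3, water_level_fluctuations: 30.0}
  - id: S_44
    description: S_34 and S_37 together
    evidence: {tourism_pressure: 0, water_level_fluctuations: 10.0}
  - id: S_45
    description: best possible scenario
    evidence:
      water_level_fluctuations: 30.0
      water_salinity: 0
      water_diversions: 0
      water_discharges: 3
      tourism_pressure: 0
  - id: S_46
    description: S_21, S_35 and S_36 together
    evidence: {water_salinity: 3, water_discharges: 3, water_diversions: 0}
  - id: S_47
    description: S_25, S_35 and S_36 together
    evidence: {water_level_fluctuations: 5.0, water_discharges: 3, water_diversions: 0}
  - id: S_48
    description: S_26, S_35 and S_36 together
    evidence: {water_level_fluctuations: 0.0, water_discharges: 3, water_diversions: 0}
  - id: S_49
    description: S_22, S_24, S_35 and S_41 together
    evidence:
      tourism_pressure: 3
      water_diversions: 3
      water_discharges: 3
      water_level_fluctuations: 30.0
  - id: S_50
    description: S_21 and S_38 together
    evidence: {water_salinity: 3, water_level_fluctuations: 15.0}
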