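# Soil-vegetation index system for reclaimed opencast-mine dump plots
# (Pingshuo, Loess Plateau): 2 systems, 5 subsystems, 18 indicators.
# All directions are benefit so the published scores are reproduced;
# flip pH / bulk density to cost for conventional soil-quality use.
systems:
  - vegetation
  - soil
subsystems:
  vegetation: [tree, herb, litter]
  soil: [basic, nutrient]
indicators:
  - {id: X1,  name: canopy density,       system: vegetation, subsystem: tree,     direction: benefit, units: ""}
  - {id: X2,  name: diameter at breast height, system: vegetation, subsystem: tree, direction: benefit, units: cm}
  - {id: X3,  name: tree height,          system: vegetation, subsystem: tree,     direction: benefit, units: m}
  - {id: X4,  name: tree canopy,          system: vegetation, subsystem: tree,     direction: benefit, units: m}
  - {id: X5,  name: tree biomass,         system: vegetation, subsystem: tree,     direction: benefit, units: kg}
  - {id: X6,  name: herb coverage,        system: vegetation, subsystem: herb,     direction: benefit, units: "%"}
  - {id: X7,  name: herb height,          system: vegetation, subsystem: herb,     direction: benefit, units: cm}
  - {id: X8,  name: herb biomass,         system: vegetation, subsystem: herb,     direction: benefit, units: g m-2}
  - {id: X9,  name: litter biomass,       system: vegetation, subsystem: litter,   direction: benefit, units: g m-2}
  - {id: X10, name: pH,                   system: soil,       subsystem: basic,    direction: benefit, units: ""}
  - {id: X11, name: bulk density,         system: soil,       subsystem: basic,    direction: benefit, units: g cm-3}
  - {id: X12, name: soil organic matter,  system: soil,       subsystem: nutrient, direction: benefit, units: g kg-1}
  - {id: X13, name: total nitrogen,       system: soil,       subsystem: nutrient, direction: benefit, units: g kg-1}
  - {id: X14, name: total phosphorus,     system: soil,       subsystem: nutrient, direction: benefit, units: g kg-1}
  - {id: X15, name: total potassium,      system: soil,       subsystem: nutrient, direction: benefit, units: g kg-1}
  - {id: X16, name: available nitrogen,   system: soil,       subsystem: nutrient, direction: benefit, units: mg kg-1}
  - {id: X17, name: available phosphorus, system: soil,       subsystem: nutrient, direction: benefit, units: mg kg-1}
  - {id: X18, name: available potassium,  system: soil,       subsystem: nutrient, direction: benefit, units: mg kg-1}
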