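# Subsystem weights for the Pingshuo index system. The original
# pairwise judgment matrices were never published; these direct
# weights are back-derived from the published combined-weight table
# by summing each subsystem's block (they are normalized on load).
vegetation:
  direct_weights:
    tree: 0.6739
    herb: 0.2255
    litter: 0.1007
soil:
  direct_weights:
    basic: 0.2000
    nutrient: 0.8001
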