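# Default fuzzy-model configuration: membership partitions, rule bases and
# iteration parameters.  The pH universe [2, 11] is the display image of the
# ODE model's proton scale; densities are normalized to carrying capacity.
# Rules: growth when the current pH label matches the species' preferred-pH
# label (and a population is present); decline one label away is slow, two
# labels away fast.  pH drive scales with the density label and follows the
# species' pH_change_ability sign (+1 raises pH).
partitions:
  pH:
    universe: [2.0, 11.0]
    mfs:
      low: [2.0, 2.0, 2.0, 6.5]
      medium: [2.0, 6.5, 6.5, 11.0]
      high: [6.5, 11.0, 11.0, 11.0]
  preferred_pH: pH
  cell_density:
    universe: [0.0, 1.0]
    mfs:
      zero: [0.0, 0.0, 0.0, 0.001]
      low: [0.0, 0.001, 0.15, 0.5]
      medium: [0.15, 0.5, 0.5, 1.0]
      high: [0.5, 1.0, 1.0, 1.0]
  cell_density_change:
    universe: [-1.0, 1.0]
    mfs:
      negative: [-0.75, -0.45, -0.45, -0.15]
      negative_small: [-0.24, -0.12, -0.12, 0.0]
      zero: [-0.08, 0.0, 0.0, 0.08]
      positive: [0.15, 0.45, 0.45, 0.75]
  pH_change_ability:
    universe: [-1.0, 1.0]
    mfs:
      negative: [-1.0, -1.0, -0.5, 0.0]
      positive: [0.0, 0.5, 1.0, 1.0]
  pH_change:
    universe: [-3.0, 3.0]
    mfs:
      negative_large: [-3.0, -2.6, -2.6, -2.2]
      negative_medium: [-2.2, -1.5, -1.5, -0.8]
      negative_small: [-1.2, -0.6, -0.6, 0.0]
      zero: [-0.2, 0.0, 0.0, 0.2]
      positive_small: [0.0, 0.6, 0.6, 1.2]
      positive_medium: [0.8, 1.5, 1.5, 2.2]
      positive_large: [2.2, 2.6, 2.6, 3.0]
density_rules:
- if:
    pH: low
    preferred_pH: low
    cell_density: [low, medium, high]
  then: positive
- if:
    pH: medium
    preferred_pH: medium
    cell_density: [low, medium, high]
  then: positive
- if:
    pH: high
    preferred_pH: high
    cell_density: [low, medium, high]
  then: positive
- if: {pH: low, preferred_pH: medium}
  then: negative_small
- if: {pH: low, preferred_pH: high}
  then: negative
- if: {pH: medium, preferred_pH: low}
  then: negative_small
- if: {pH: medium, preferred_pH: high}
  then: negative_small
- if: {pH: high, preferred_pH: low}
  then: negative
- if: {pH: high, preferred_pH: medium}
  then: negative_small
- if: {cell_density: zero}
  then: zero
ph_rules:
- if: {cell_density: zero}
  then: zero
- if: {cell_density: low, pH_change_ability: positive}
  then: positive_small
- if: {cell_density: low, pH_change_ability: negative}
  then: negative_small
- if: {cell_density: medium, pH_change_ability: positive}
  then: positive_medium
- if: {cell_density: medium, pH_change_ability: negative}
  then: negative_medium
- if: {cell_density: high, pH_change_ability: positive}
  then: positive_large
- if: {cell_density: high, pH_change_ability: negative}
  then: negative_large
gain: 0.05
n_iterations: 200
relative_strength: 1.0
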