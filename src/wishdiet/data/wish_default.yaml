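# Default WISH registry: the 13 EAT-Lancet food groups with their published
# recommended intakes (g/day), lower/upper ranges, health and environmental
# classifications, and piecewise-linear scoring shapes.
#
# For RAMP_UP_OPEN components the upper range value is stored for reference
# but the scoring rule models no upper restriction. The whole-grains
# recommended intake (125 g/day) follows the Global Burden of Disease
# recommendation rather than the energy-adjusted EAT-Lancet amount.
components:
  - id: whole_grains
    health_class: protective
    env_class: low
    lower: 100
    recommended: 125
    upper: 150
    shape: RAMP_UP_OPEN
  - id: vegetables
    health_class: protective
    env_class: low
    lower: 200
    recommended: 300
    upper: 600
    shape: RAMP_UP_OPEN
  - id: fruits
    health_class: protective
    env_class: low
    lower: 100
    recommended: 200
    upper: 300
    shape: RAMP_UP_OPEN
  - id: dairy
    health_class: protective
    env_class: medium
    lower: 0
    recommended: 250
    upper: 500
    shape: OPTIMUM_BAND
  - id: red_meat
    health_class: limit
    env_class: high
    lower: 0
    recommended: 14
    upper: 28
    shape: RAMP_DOWN
  - id: fish
    health_class: protective
    env_class: high
    lower: 0
    recommended: 28
    upper: 100
    shape: OPTIMUM_BAND
  - id: eggs
    health_class: neutral
    env_class: medium
    lower: 0
    recommended: 13
    upper: 25
    shape: RAMP_DOWN
  - id: poultry
    health_class: neutral
    env_class: medium
    lower: 0
    recommended: 29
    upper: 58
    shape: RAMP_DOWN
  - id: legumes
    health_class: protective
    env_class: low
    lower: 0
    recommended: 75
    upper: 100
    shape: RAMP_UP_OPEN
  - id: nuts
    health_class: protective
    env_class: medium
    lower: 0
    recommended: 50
    upper: 75
    shape: OPTIMUM_BAND
  - id: unsat_oils
    health_class: protective
    env_class: low
    lower: 20
    recommended: 40
    upper: 80
    shape: RAMP_UP_CAPPED
  - id: sat_oils
    health_class: limit
    env_class: high
    lower: 0
    recommended: 11.8
    upper: 11.8
    shape: BIVARIATE_LIMIT
  - id: added_sugars
    health_class: limit
    env_class: low
    lower: 0
    recommended: 31
    upper: 31
    shape: BIVARIATE_LIMIT

subscores:
  healthy:
    - whole_grains
    - vegetables
    - fruits
    - dairy
    - fish
    - eggs
    - poultry
    - legumes
    - nuts
    - unsat_oils
  less_healthy:
    - red_meat
    - sat_oils
    - added_sugars
  low_env:
    - whole_grains
    - vegetables
    - fruits
    - legumes
    - unsat_oils
    - added_sugars
  high_env:
    - sat_oils
    - dairy
    - red_meat
    - fish
    - eggs
    - poultry
    - nuts
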