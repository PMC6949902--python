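groups:
  total_vegetables:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 3.0
      points: 0
    - lower: 3.0
      upper: 5.0
      points: 1
    - lower: 5.0
      upper: .inf
      points: 2
  dark_green_leafy_vegetables:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 0.5
      points: 0
    - lower: 0.5
      upper: 1.0
      points: 1
    - lower: 1.0
      upper: .inf
      points: 2
  fruit:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 1.0
      points: 0
    - lower: 1.0
      upper: 2.0
      points: 1
    - lower: 2.0
      upper: .inf
      points: 2
  water:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 4.0
      points: 0
    - lower: 4.0
      upper: 6.0
      points: 1
    - lower: 6.0
      upper: .inf
      points: 2
  red_meat:
    direction: moderation
    bands:
    - lower: 0.0
      upper: 0.5
      points: 2
    - lower: 0.5
      upper: 1.0
      points: 1
    - lower: 1.0
      upper: .inf
      points: 0
  processed_meat:
    direction: moderation
    bands:
    - lower: 0.0
      upper: 0.02
      points: 2
    - lower: 0.02
      upper: 0.15
      points: 1
    - lower: 0.15
      upper: .inf
      points: 0
  fish_seafood:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 0.14
      points: 0
    - lower: 0.14
      upper: 0.28
      points: 1
    - lower: 0.28
      upper: .inf
      points: 2
  legumes:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 0.14
      points: 0
    - lower: 0.14
      upper: 0.28
      points: 1
    - lower: 0.28
      upper: .inf
      points: 2
  nuts:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 0.28
      points: 0
    - lower: 0.28
      upper: 0.7
      points: 1
    - lower: 0.7
      upper: .inf
      points: 2
  eggs:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 0.28
      points: 0
    - lower: 0.28
      upper: 0.85
      points: 1
    - lower: 0.85
      upper: .inf
      points: 2
  low_gi_cereals:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 1.0
      points: 0
    - lower: 1.0
      upper: 2.0
      points: 1
    - lower: 2.0
      upper: .inf
      points: 2
  high_gi_cereals:
    direction: moderation
    bands:
    - lower: 0.0
      upper: 0.5
      points: 2
    - lower: 0.5
      upper: 1.5
      points: 1
    - lower: 1.5
      upper: .inf
      points: 0
  discretionary:
    direction: moderation
    bands:
    - lower: 0.0
      upper: 0.5
      points: 2
    - lower: 0.5
      upper: 1.5
      points: 1
    - lower: 1.5
      upper: .inf
      points: 0
  alcohol:
    direction: moderation
    bands:
    - lower: 0.0
      upper: 1.0
      points: 2
    - lower: 1.0
      upper: 2.0
      points: 1
    - lower: 2.0
      upper: .inf
      points: 0
  fats_oils:
    direction: adequacy
    bands:
    - lower: 0.0
      upper: 0.5
      points: 0
    - lower: 0.5
      upper: 1.0
      points: 1
    - lower: 1.0
      upper: .inf
      points: 2
max_total: 30
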