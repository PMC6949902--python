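entries:
- name: rolled oats
  food_group: low_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 480.0
  gi_class: low
- name: quick oats
  food_group: low_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 480.0
  gi_class: low
- name: natural muesli
  food_group: low_gi_cereals
  serve_mass_g: 45.0
  energy_kj_per_serve: 700.0
  gi_class: low
- name: toasted muesli
  food_group: low_gi_cereals
  serve_mass_g: 45.0
  energy_kj_per_serve: 820.0
  gi_class: low
- name: bran flakes
  food_group: low_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 430.0
  gi_class: low
- name: oat bran
  food_group: low_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 420.0
  gi_class: low
- name: granola
  food_group: low_gi_cereals
  serve_mass_g: 45.0
  energy_kj_per_serve: 850.0
  gi_class: low
- name: cornflakes
  food_group: high_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 480.0
  gi_class: high
- name: rice bubbles
  food_group: high_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 470.0
  gi_class: high
- name: wheat biscuit cereal
  food_group: high_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 450.0
  gi_class: high
- name: puffed wheat
  food_group: high_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 440.0
  gi_class: high
- name: instant porridge
  food_group: high_gi_cereals
  serve_mass_g: 30.0
  energy_kj_per_serve: 470.0
  gi_class: high
- name: olive oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: extra virgin olive oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: canola oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: sunflower oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: vegetable oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: coconut oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: rice bran oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
- name: grapeseed oil
  food_group: fats_oils
  serve_mass_g: 10.0
  energy_kj_per_serve: 370.0
  gi_class: na
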