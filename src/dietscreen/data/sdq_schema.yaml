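kind: sdq
name: 36-item short dietary questionnaire (synthetic, structurally faithful)
items:
- item_id: sdq_fruit_fresh
  food_group: fruit
  unit: serves_per_day
  drink_type: null
- item_id: sdq_fruit_other
  food_group: fruit
  unit: serves_per_day
  drink_type: null
- item_id: sdq_vegetables_cooked
  food_group: total_vegetables
  unit: serves_per_day
  drink_type: null
- item_id: sdq_vegetables_raw_salad
  food_group: total_vegetables
  unit: serves_per_day
  drink_type: null
- item_id: sdq_dark_green_leafy
  food_group: dark_green_leafy_vegetables
  unit: serves_per_day
  drink_type: null
- item_id: sdq_water
  food_group: water
  unit: serves_per_day
  drink_type: null
- item_id: sdq_beef
  food_group: red_meat
  unit: serves_per_week
  drink_type: null
- item_id: sdq_lamb
  food_group: red_meat
  unit: serves_per_week
  drink_type: null
- item_id: sdq_pork
  food_group: red_meat
  unit: serves_per_week
  drink_type: null
- item_id: sdq_ham_bacon
  food_group: processed_meat
  unit: serves_per_week
  drink_type: null
- item_id: sdq_other_processed_meat
  food_group: processed_meat
  unit: serves_per_week
  drink_type: null
- item_id: sdq_chicken
  food_group: white_meat
  unit: serves_per_week
  drink_type: null
- item_id: sdq_fish_fresh
  food_group: fish_seafood
  unit: serves_per_week
  drink_type: null
- item_id: sdq_fish_canned
  food_group: fish_seafood
  unit: serves_per_week
  drink_type: null
- item_id: sdq_other_seafood
  food_group: fish_seafood
  unit: serves_per_week
  drink_type: null
- item_id: sdq_legumes
  food_group: legumes
  unit: serves_per_week
  drink_type: null
- item_id: sdq_nuts
  food_group: nuts
  unit: serves_per_week
  drink_type: null
- item_id: sdq_eggs
  food_group: eggs
  unit: serves_per_week
  drink_type: null
- item_id: sdq_white_bread
  food_group: high_gi_cereals
  unit: times_per_week
  drink_type: null
- item_id: sdq_wholegrain_bread
  food_group: low_gi_cereals
  unit: times_per_week
  drink_type: null
- item_id: sdq_rice
  food_group: high_gi_cereals
  unit: times_per_week
  drink_type: null
- item_id: sdq_pasta
  food_group: low_gi_cereals
  unit: times_per_week
  drink_type: null
- item_id: sdq_cereal_high_gi
  food_group: high_gi_cereals
  unit: times_per_week
  drink_type: null
- item_id: sdq_cereal_low_gi
  food_group: low_gi_cereals
  unit: times_per_week
  drink_type: null
- item_id: sdq_biscuits
  food_group: discretionary
  unit: times_per_week
  drink_type: null
- item_id: sdq_cakes
  food_group: discretionary
  unit: times_per_week
  drink_type: null
- item_id: sdq_ice_cream
  food_group: discretionary
  unit: times_per_week
  drink_type: null
- item_id: sdq_sugary_drinks
  food_group: discretionary
  unit: times_per_week
  drink_type: null
- item_id: sdq_takeaway
  food_group: discretionary
  unit: times_per_week
  drink_type: null
- item_id: sdq_processed_potato
  food_group: discretionary
  unit: times_per_week
  drink_type: null
- item_id: sdq_beer
  food_group: alcohol
  unit: times_per_week
  drink_type: beer
- item_id: sdq_wine
  food_group: alcohol
  unit: times_per_week
  drink_type: wine
- item_id: sdq_spirits
  food_group: alcohol
  unit: times_per_week
  drink_type: spirits
- item_id: sdq_butter
  food_group: fats_oils
  unit: times_per_week
  drink_type: null
- item_id: sdq_margarine
  food_group: fats_oils
  unit: times_per_week
  drink_type: null
- item_id: sdq_cooking_oil
  food_group: fats_oils
  unit: times_per_week
  drink_type: null
frequency_map:
  options:
  - - Never
    - 0.0
  - - Less than 1 per month
    - 0.02
  - - 1–3 per month
    - 0.07
  - - 1 per week
    - 0.14
  - - 2–4 per week
    - 0.43
  - - 5–6 per week
    - 0.79
  - - 1 per day
    - 1.0
  - - 2–3 per day
    - 2.5
  - - 4+ per day
    - 4.0
group_serve_mass_g: {}
discretionary_kj_per_serve: 600.0
alcohol_g_per_serve: 10.0
drinks:
  beer:
    ethanol_g_per_reported_drink: 13.6
  wine:
    ethanol_g_per_reported_drink: 15.4
  spirits:
    ethanol_g_per_reported_drink: 10.0
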