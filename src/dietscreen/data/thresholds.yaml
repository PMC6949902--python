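negligible_r: 0.3
alpha: 0.05
age_cut_years: 80
loa_sd_multiplier: 2.0
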