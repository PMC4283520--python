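biomass_id: EX_W
min_biomass_fraction: 0.1
min_product_fraction: 0.9
name: aerobic-like
product_id: EX_P
rules: []
uptake_bounds:
  UPT:
  - -100.0
  - -100.0
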