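# Heterotrophic growth: acetate in the dark (oxygen-limited).
condition: heterotrophic
fixed_growth_rate: 0.035   # h^-1
substrate_exchange: EX_ac_e
product_exchange: EX_h2_e
objective_1: [EX_ac_e, minimize uptake]
objective_2: [EX_h2_e, maximize]
bound_overrides:
  EX_photon_e: [0.0, 0.0]        # photons -
  EX_co2_e: [0.0, 1000.0]        # CO2 uptake - (respiratory venting open)
  EX_ac_e: [-1.5, 1000.0]        # acetate uptake +
  EX_o2_e: [-2.0, 1000.0]        # dark O2 cap
  ATPM_c: [0.2, 1000.0]
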