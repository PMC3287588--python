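# Autotrophic growth: photons + CO2, no acetate.
condition: autotrophic
fixed_growth_rate: 0.059   # h^-1
substrate_exchange: EX_photon_e
product_exchange: EX_h2_e
objective_1: [EX_photon_e, minimize uptake]
objective_2: [EX_h2_e, maximize]
bound_overrides:
  EX_photon_e: [-1000.0, 0.0]    # free photon uptake
  EX_co2_e: [-1000.0, 1000.0]    # CO2 uptake +
  EX_ac_e: [0.0, 1000.0]         # acetate uptake -
  EX_o2_e: [-1000.0, 1000.0]
  ATPM_c: [0.2, 1000.0]          # non-growth maintenance
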